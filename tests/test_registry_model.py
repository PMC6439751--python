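"""Registry data model: phenotype mapping, exclusions, person-time,
exposure classification and prevalence summaries."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from adoptherit.registry_model import (
    DEFAULT_CODE_MAP,
    ExclusionRules,
    apply_adoptee_exclusions,
    classify_exposure,
    compute_person_time,
    map_phenotypes,
    summarize_prevalence,
)
from conftest import persons_frame


def dx(person, version, code, date="2005-06-01", source="outpatient"):
    return {
        "person_id": person,
        "icd_version": version,
        "code": code,
        "diagnosis_date": pd.Timestamp(date),
        "source": source,
    }


class TestMapPhenotypes:
    @pytest.mark.parametrize(
        "version, code, expected",
        [
            (10, "H931", True),
            (9, "388D", True),
            (8, "781.31", True),
            (7, "781.32", True),
            (10, "H930", False),
            (9, "H931", False),  # code must match within its revision
        ],
    )
    def test_tinnitus_code_matching(self, version, code, expected):
        records = pd.DataFrame([dx("p1", version, code)])
        flags = map_phenotypes(records, DEFAULT_CODE_MAP)
        assert bool(flags.loc["p1", "tinnitus"]) is expected

    def test_whitespace_trimmed_before_matching(self):
        records = pd.DataFrame([dx("p1", 10, "  H931 ")])
        assert bool(map_phenotypes(records).loc["p1", "tinnitus"])

    def test_first_date_is_earliest_match(self):
        records = pd.DataFrame(
            [
                dx("p1", 10, "H931", "2010-01-01"),
                dx("p1", 9, "388D", "1990-05-05"),
                dx("p1", 10, "H930", "1980-01-01"),  # non-matching
            ]
        )
        flags = map_phenotypes(records)
        assert flags.loc["p1", "tinnitus_first_date"] == pd.Timestamp(
            "1990-05-05"
        )

    def test_unknown_icd_version_dropped_with_warning(self):
        records = pd.DataFrame(
            [dx("p1", 11, "H931"), dx("p2", 10, "H931")]
        )
        with pytest.warns(UserWarning, match="unknown ICD version"):
            flags = map_phenotypes(records)
        assert not flags.loc["p1", "tinnitus"]
        assert flags.loc["p2", "tinnitus"]

    def test_order_independent_and_idempotent(self):
        records = pd.DataFrame(
            [
                dx("p1", 10, "H931", "2010-01-01"),
                dx("p2", 9, "388D", "2001-01-01"),
                dx("p1", 8, "781.31", "1985-01-01"),
            ]
        )
        shuffled = records.sample(frac=1.0, random_state=1)
        a = map_phenotypes(records)
        b = map_phenotypes(shuffled)
        pd.testing.assert_frame_equal(a, b)


def links_frame(rows):
    return pd.DataFrame(rows, columns=["adoptee_id", "parent_id",
                                       "link_kind"])


FULL_LINKS = links_frame(
    [("a1", "b1", "biological"), ("a1", "p1", "adoptive")]
)


class TestExclusions:
    def test_death_before_16_excluded(self):
        persons = persons_frame(
            [{"person_id": "a1", "birth_date": "1970-01-01",
              "death_date": "1980-01-01"}]
        )
        _, excluded, tally = apply_adoptee_exclusions(persons, FULL_LINKS)
        assert tally["died_before_16"] == 1
        assert excluded.iloc[0]["reason"] == "died_before_16"

    def test_emigration_before_16_excluded(self):
        persons = persons_frame(
            [{"person_id": "a1", "birth_date": "1970-01-01",
              "emigration_date": "1975-01-01"}]
        )
        _, _, tally = apply_adoptee_exclusions(persons, FULL_LINKS)
        assert tally["emigrated_before_16"] == 1

    def test_missing_link_excluded_not_error(self):
        persons = persons_frame(
            [{"person_id": "a1"}, {"person_id": "a2"}]
        )
        links = links_frame([("a1", "b1", "biological")])  # a2 unlinked
        retained, _, tally = apply_adoptee_exclusions(persons, links)
        assert tally["missing_parent_link"] == 2
        assert retained.empty

    def test_cohabitation_with_biological_parent_excluded(self):
        persons = persons_frame(
            [{"person_id": "a1", "birth_date": "1970-01-01"}]
        )
        residency = pd.DataFrame(
            [
                {"person_id": "a1", "area_code": "X1",
                 "start_year": 1970, "end_year": 1972},
                {"person_id": "b1", "area_code": "X1",
                 "start_year": 1960, "end_year": 1990},
            ]
        )
        _, _, tally = apply_adoptee_exclusions(
            persons, FULL_LINKS, residency
        )
        assert tally["cohabited_with_biological"] == 1

    def test_shared_area_after_age_16_not_cohabitation(self):
        persons = persons_frame(
            [{"person_id": "a1", "birth_date": "1970-01-01"}]
        )
        residency = pd.DataFrame(
            [
                {"person_id": "a1", "area_code": "X1",
                 "start_year": 1990, "end_year": 1995},
                {"person_id": "b1", "area_code": "X1",
                 "start_year": 1990, "end_year": 1995},
            ]
        )
        retained, _, _ = apply_adoptee_exclusions(
            persons, FULL_LINKS, residency
        )
        assert list(retained["person_id"]) == ["a1"]

    def test_first_hit_rule_wins(self):
        # died young AND missing links: tallied only under death rule
        persons = persons_frame(
            [{"person_id": "a1", "birth_date": "1970-01-01",
              "death_date": "1975-01-01"}]
        )
        _, _, tally = apply_adoptee_exclusions(persons, links_frame([]))
        assert tally["died_before_16"] == 1
        assert tally["missing_parent_link"] == 0

    def test_clean_fixture_retains_everyone(self):
        persons = persons_frame(
            [{"person_id": f"a{i}"} for i in range(10)]
        )
        links = links_frame(
            sum(
                (
                    [(f"a{i}", f"b{i}", "biological"),
                     (f"a{i}", f"p{i}", "adoptive")]
                    for i in range(10)
                ),
                [],
            )
        )
        retained, excluded, tally = apply_adoptee_exclusions(
            persons, links
        )
        assert len(retained) == 10
        assert excluded.empty
        assert all(v == 0 for v in tally.values())

    def test_tallies_partition_input(self):
        persons = persons_frame(
            [
                {"person_id": "a1", "death_date": "1970-01-01",
                 "birth_date": "1965-01-01"},
                {"person_id": "a2"},
                {"person_id": "a3"},
            ]
        )
        links = links_frame(
            [("a2", "b2", "biological"), ("a2", "p2", "adoptive")]
        )
        retained, excluded, tally = apply_adoptee_exclusions(
            persons, links
        )
        assert len(retained) + sum(tally.values()) == 3
        assert len(excluded) == sum(tally.values())

    def test_rules_can_be_disabled(self):
        persons = persons_frame(
            [{"person_id": "a1", "birth_date": "1970-01-01",
              "death_date": "1975-06-01"}]
        )
        rules = ExclusionRules(died_before_16=False,
                               missing_parent_link=False)
        retained, _, _ = apply_adoptee_exclusions(
            persons, links_frame([]), rules=rules
        )
        assert len(retained) == 1


class TestPersonTime:
    def test_diagnosis_truncates_follow_up(self):
        assert compute_person_time(
            "1965-01-01", first_tinnitus_date="2005-01-01"
        ) == pytest.approx(40.0, abs=0.01)

    def test_uncensored_runs_to_study_end(self):
        assert compute_person_time("1970-07-01") == pytest.approx(
            45.5, abs=0.01
        )

    def test_earliest_event_wins(self):
        full = compute_person_time("1970-01-01", death_date="2010-01-01")
        shorter = compute_person_time(
            "1970-01-01", death_date="2010-01-01",
            emigration_date="2000-01-01",
        )
        assert shorter < full

    def test_corrupt_dates_error(self):
        with pytest.raises(ValueError):
            compute_person_time("1960-01-01", death_date="1959-06-01")

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(delta=st.integers(0, 10_000))
    def test_monotone_in_censoring_date(self, delta):
        base = pd.Timestamp("2010-01-01")
        later = compute_person_time("1970-01-01", death_date=base)
        earlier = compute_person_time(
            "1970-01-01", death_date=base - pd.Timedelta(days=delta)
        )
        assert earlier <= later


class TestExposure:
    def make_flags(self, affected):
        return pd.DataFrame(
            {"tinnitus": affected},
            index=pd.Index(list(affected), name="person_id"),
        )

    def test_one_of_two_bio_parents_sets_flag(self):
        links = links_frame(
            [("a1", "b1", "biological"), ("a1", "b2", "biological"),
             ("a1", "p1", "adoptive")]
        )
        flags = self.make_flags({"b1": True, "b2": False, "p1": False})
        out = classify_exposure(links, flags)
        assert bool(out.loc["a1", "exposure_bio"])
        assert not bool(out.loc["a1", "exposure_adopt"])

    def test_no_affected_parents_both_false(self):
        flags = self.make_flags({"b1": False, "p1": False})
        out = classify_exposure(FULL_LINKS, flags)
        assert not out.loc["a1"].any()

    def test_flags_are_independent(self):
        flags = self.make_flags({"b1": True, "p1": True})
        out = classify_exposure(FULL_LINKS, flags)
        assert bool(out.loc["a1", "exposure_bio"])
        assert bool(out.loc["a1", "exposure_adopt"])

    def test_unknown_parent_id_raises(self):
        flags = self.make_flags({"b1": True})
        with pytest.raises(KeyError):
            classify_exposure(FULL_LINKS, flags)


class TestPrevalenceSummary:
    def test_counts_and_percent(self):
        df = pd.DataFrame(
            {
                "role": ["adoptee"] * 4 + ["biological_parent"] * 3,
                "tinnitus": [True, False, False, False, True, True, False],
            }
        )
        out = summarize_prevalence(df).set_index("role")
        assert out.loc["adoptee", "percent"] == 25.0
        assert out.loc["biological_parent", "cases"] == 2

    def test_zero_cases_zero_percent(self):
        df = pd.DataFrame({"role": ["adoptee"] * 5, "tinnitus": [False] * 5})
        out = summarize_prevalence(df)
        assert out["percent"].iloc[0] == 0.0
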