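"""Registry-shaped data model: readers, ICD phenotype extraction,
adoptee exclusion filtering, exposure classification and person-time.

The analysis consumes four delimited tables mirroring national-register
extracts:

``persons.csv``
    person_id, role (adoptee | biological_parent | adoptive_parent), sex
    (female | male), birth_date, death_date, emigration_date,
    county_of_birth, education (low | middle | high | unknown)
``links.csv``
    adoptee_id, parent_id, link_kind (biological | adoptive)
``diagnoses.csv``
    person_id, icd_version (7 | 8 | 9 | 10), code, diagnosis_date,
    source (hospital_discharge | outpatient | primary_care)
``residency.csv``
    person_id, area_code, start_year, end_year

Dates are ISO calendar dates; year arithmetic uses exact day counts
divided by 365.25.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "DEFAULT_CODE_MAP",
    "DEFAULT_COVERAGE",
    "STUDY_END",
    "FOLLOW_UP_START_YEAR",
    "SchemaError",
    "ExclusionRules",
    "read_persons",
    "read_links",
    "read_diagnoses",
    "read_residency",
    "load_code_map",
    "map_phenotypes",
    "apply_adoptee_exclusions",
    "compute_person_time",
    "classify_exposure",
    "summarize_prevalence",
    "build_cohort",
]

#: Tinnitus ICD map across revisions 7-10. Comorbidity maps (depression,
#: anxiety, hearing loss) are study-specific and user-supplied.
DEFAULT_CODE_MAP: dict[str, list[tuple[int, str]]] = {
    "tinnitus": [(7, "781.32"), (8, "781.31"), (9, "388D"), (10, "H931")],
}

#: Register coverage windows by diagnosis source (inclusive years).
DEFAULT_COVERAGE: dict[str, tuple[int, int]] = {
    "hospital_discharge": (1964, 2015),
    "outpatient": (2001, 2015),
    "primary_care": (1997, 2015),
}

STUDY_END = pd.Timestamp("2015-12-31")
FOLLOW_UP_START_YEAR = 1964

DAYS_PER_YEAR = 365.25

_ROLES = {"adoptee", "biological_parent", "adoptive_parent"}
_EDUCATION = {"low", "middle", "high", "unknown"}

_SCHEMAS = {
    "persons": [
        "person_id", "role", "sex", "birth_date", "death_date",
        "emigration_date", "county_of_birth", "education",
    ],
    "links": ["adoptee_id", "parent_id", "link_kind"],
    "diagnoses": [
        "person_id", "icd_version", "code", "diagnosis_date", "source",
    ],
    "residency": ["person_id", "area_code", "start_year", "end_year"],
}


class SchemaError(ValueError):
    """An input table is missing required columns or violates a basic
    invariant; the message names the offending columns."""


def _check_columns(df: pd.DataFrame, table: str) -> None:
    missing = [c for c in _SCHEMAS[table] if c not in df.columns]
    if missing:
        raise SchemaError(
            f"{table} table is missing required column(s): "
            + ", ".join(missing)
        )


def read_persons(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "county_of_birth": str})
    _check_columns(df, "persons")
    for col in ("birth_date", "death_date", "emigration_date"):
        df[col] = pd.to_datetime(df[col], format="%Y-%m-%d")
    bad_role = set(df["role"]) - _ROLES
    if bad_role:
        raise SchemaError(f"persons.role has unknown values: {bad_role}")
    bad_edu = set(df["education"]) - _EDUCATION
    if bad_edu:
        raise SchemaError(f"persons.education has unknown values: {bad_edu}")
    for col in ("death_date", "emigration_date"):
        bad = df[col].notna() & (df[col] < df["birth_date"])
        if bad.any():
            raise SchemaError(
                f"persons.{col} precedes birth_date for "
                f"{int(bad.sum())} row(s)"
            )
    return df


def read_links(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype=str)
    _check_columns(df, "links")
    bad = set(df["link_kind"]) - {"biological", "adoptive"}
    if bad:
        raise SchemaError(f"links.link_kind has unknown values: {bad}")
    return df


def read_diagnoses(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "code": str})
    _check_columns(df, "diagnoses")
    df["diagnosis_date"] = pd.to_datetime(
        df["diagnosis_date"], format="%Y-%m-%d"
    )
    return df


def read_residency(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"person_id": str, "area_code": str})
    _check_columns(df, "residency")
    if (df["start_year"] > df["end_year"]).any():
        raise SchemaError("residency has rows with start_year > end_year")
    return df


def load_code_map(path: str | Path) -> dict[str, list[tuple[int, str]]]:
    """Read a phenotype -> [(icd_version, code), ...] map from YAML or
    JSON (``{"tinnitus": [[10, "H931"], ...], ...}``)."""
    text = Path(path).read_text()
    raw = (
        json.loads(text)
        if str(path).endswith(".json")
        else yaml.safe_load(text)
    )
    return {
        pheno: [(int(v), str(c)) for v, c in pairs]
        for pheno, pairs in raw.items()
    }


def map_phenotypes(
    records: pd.DataFrame,
    code_map: dict[str, list[tuple[int, str]]] | None = None,
) -> pd.DataFrame:
    """Per-person phenotype flags and first diagnosis dates.

    A person is phenotype-positive if at least one record matches any
    mapped (icd_version, code) pair; matching is exact string comparison
    after trimming whitespace, per ICD revision.  Records with an ICD
    version outside {7, 8, 9, 10} are dropped with a warning.

    Returns a frame indexed by person_id with a boolean column per
    phenotype plus ``{phenotype}_first_date``.
    """
    if code_map is None:
        code_map = DEFAULT_CODE_MAP
    df = records.copy()
    known = df["icd_version"].isin([7, 8, 9, 10])
    if not known.all():
        bad = sorted(df.loc[~known, "icd_version"].unique().tolist())
        warnings.warn(
            f"dropping {int((~known).sum())} diagnosis record(s) with "
            f"unknown ICD version(s) {bad}",
            stacklevel=2,
        )
        df = df[known]
    df = df.assign(code=df["code"].str.strip())

    out = pd.DataFrame(index=pd.Index(sorted(records["person_id"].unique()),
                                      name="person_id"))
    for pheno, pairs in code_map.items():
        mask = pd.Series(False, index=df.index)
        for version, code in pairs:
            mask |= (df["icd_version"] == version) & (df["code"] == code)
        first = (
            df[mask].groupby("person_id")["diagnosis_date"].min()
        )
        out[pheno] = out.index.isin(first.index)
        out[f"{pheno}_first_date"] = first.reindex(out.index)
    return out


@dataclass(frozen=True)
class ExclusionRules:
    """Adoptee exclusion switches, applied in field order with each
    adoptee tallied under the first rule that hits."""

    died_before_16: bool = True
    emigrated_before_16: bool = True
    died_before_start: bool = True
    missing_parent_link: bool = True
    cohabited_with_biological: bool = True
    follow_up_start_year: int = FOLLOW_UP_START_YEAR
    cohabitation_age_limit: int = 16


EXCLUSION_ORDER = (
    "died_before_16",
    "emigrated_before_16",
    "died_before_start",
    "missing_parent_link",
    "cohabited_with_biological",
)


def _age_at(event: pd.Series, birth: pd.Series) -> pd.Series:
    return (event - birth).dt.days / DAYS_PER_YEAR


def _cohabited_ids(
    adoptees: pd.DataFrame,
    links: pd.DataFrame,
    residency: pd.DataFrame,
    age_limit: int,
) -> set[str]:
    """Adoptees sharing an (area_code, year) with a linked biological
    parent before the given age; residency rows are year ranges."""
    bio = links[links["link_kind"] == "biological"][
        ["adoptee_id", "parent_id"]
    ]
    ad_res = residency.merge(
        adoptees[["person_id", "birth_date"]], on="person_id"
    ).rename(columns={"person_id": "adoptee_id"})
    # only residency before the adoptee's age limit can disqualify
    ad_res["cutoff_year"] = ad_res["birth_date"].dt.year + age_limit
    ad_res = ad_res[ad_res["start_year"] < ad_res["cutoff_year"]]
    par_res = residency.rename(
        columns={
            "person_id": "parent_id",
            "start_year": "p_start",
            "end_year": "p_end",
        }
    )
    joined = (
        bio.merge(ad_res, on="adoptee_id")
        .merge(par_res, on=["parent_id", "area_code"])
    )
    overlap = (
        (joined["start_year"] <= joined["p_end"])
        & (joined["p_start"] <= joined["end_year"])
        & (joined["p_start"] < joined["cutoff_year"])
    )
    return set(joined.loc[overlap, "adoptee_id"])


def apply_adoptee_exclusions(
    persons: pd.DataFrame,
    links: pd.DataFrame,
    residency: pd.DataFrame | None = None,
    rules: ExclusionRules | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Filter adoptees by the study's exclusion rules.

    Returns ``(retained_adoptees, exclusions, tally)`` where
    ``exclusions`` has one row per excluded adoptee with the first rule
    that hit, and ``tally`` counts exclusions per rule.  Retained count
    plus the tally total always equals the input adoptee count.
    """
    if rules is None:
        rules = ExclusionRules()
    adoptees = persons[persons["role"] == "adoptee"].copy()
    start = pd.Timestamp(year=rules.follow_up_start_year, month=1, day=1)

    reason = pd.Series(pd.NA, index=adoptees.index, dtype="object")
    death_age = _age_at(adoptees["death_date"], adoptees["birth_date"])
    emig_age = _age_at(adoptees["emigration_date"], adoptees["birth_date"])

    checks: dict[str, pd.Series] = {}
    checks["died_before_16"] = (
        adoptees["death_date"].notna() & (death_age < 16)
        if rules.died_before_16
        else pd.Series(False, index=adoptees.index)
    )
    checks["emigrated_before_16"] = (
        adoptees["emigration_date"].notna() & (emig_age < 16)
        if rules.emigrated_before_16
        else pd.Series(False, index=adoptees.index)
    )
    checks["died_before_start"] = (
        adoptees["death_date"].notna() & (adoptees["death_date"] < start)
        if rules.died_before_start
        else pd.Series(False, index=adoptees.index)
    )
    if rules.missing_parent_link:
        kinds = links.groupby("adoptee_id")["link_kind"].agg(set)
        has_both = adoptees["person_id"].map(
            lambda i: {"biological", "adoptive"} <= kinds.get(i, set())
        )
        checks["missing_parent_link"] = ~has_both
    else:
        checks["missing_parent_link"] = pd.Series(False,
                                                  index=adoptees.index)
    if rules.cohabited_with_biological and residency is not None:
        cohab = _cohabited_ids(
            adoptees, links, residency, rules.cohabitation_age_limit
        )
        checks["cohabited_with_biological"] = adoptees["person_id"].isin(
            cohab
        )
    else:
        checks["cohabited_with_biological"] = pd.Series(
            False, index=adoptees.index
        )

    for rule in EXCLUSION_ORDER:
        hit = checks[rule] & reason.isna()
        reason[hit] = rule

    excluded = adoptees[reason.notna()].assign(reason=reason[reason.notna()])
    retained = adoptees[reason.isna()].copy()
    tally = {rule: int((reason == rule).sum()) for rule in EXCLUSION_ORDER}
    return retained, excluded[["person_id", "reason"]], tally


def compute_person_time(
    birth_date,
    first_tinnitus_date=None,
    death_date=None,
    emigration_date=None,
    study_end=STUDY_END,
) -> float:
    """Follow-up years from birth to the earliest of first diagnosis,
    death, emigration, or the study end."""
    birth = pd.Timestamp(birth_date)
    candidates = [pd.Timestamp(study_end)]
    for d in (first_tinnitus_date, death_date, emigration_date):
        if d is not None and not pd.isna(d):
            candidates.append(pd.Timestamp(d))
    end = min(candidates)
    if end < birth:
        raise ValueError(
            f"follow-up end {end.date()} precedes birth {birth.date()}"
        )
    return (end - birth).days / DAYS_PER_YEAR


def classify_exposure(
    links: pd.DataFrame,
    parent_phenotypes: pd.DataFrame,
    phenotype: str = "tinnitus",
) -> pd.DataFrame:
    """Time-invariant parental exposure flags per adoptee.

    ``exposure_bio`` is true iff at least one linked biological parent is
    phenotype-positive (ever diagnosed during follow-up); ``exposure_adopt``
    analogously for adoptive parents.  The flags are independent: an
    adoptee can carry both.
    """
    unknown = set(links["parent_id"]) - set(parent_phenotypes.index)
    if unknown:
        raise KeyError(
            f"links reference {len(unknown)} parent_id(s) absent from the "
            f"phenotype table, e.g. {sorted(unknown)[:3]}"
        )
    flagged = links.assign(
        affected=links["parent_id"]
        .map(parent_phenotypes[phenotype])
        .astype(bool)
    )
    agg = (
        flagged.groupby(["adoptee_id", "link_kind"])["affected"]
        .any()
        .unstack(fill_value=False)
    )
    out = pd.DataFrame(index=agg.index)
    out["exposure_bio"] = agg.get(
        "biological", pd.Series(False, index=agg.index)
    )
    out["exposure_adopt"] = agg.get(
        "adoptive", pd.Series(False, index=agg.index)
    )
    return out


def summarize_prevalence(
    persons_with_flags: pd.DataFrame, phenotype: str = "tinnitus"
) -> pd.DataFrame:
    """Per-role case counts and percentages (two decimals), Table-1 style."""
    grp = persons_with_flags.groupby("role")[phenotype]
    out = pd.DataFrame(
        {"n": grp.size(), "cases": grp.sum().astype(int)}
    )
    out["percent"] = (100.0 * out["cases"] / out["n"]).round(2)
    return out.reset_index()


def build_cohort(
    persons: pd.DataFrame,
    links: pd.DataFrame,
    diagnoses: pd.DataFrame,
    residency: pd.DataFrame | None = None,
    code_map: dict[str, list[tuple[int, str]]] | None = None,
    rules: ExclusionRules | None = None,
    study_end=STUDY_END,
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, int]]:
    """Assemble the analysis cohort: retained adoptees with phenotype
    flags, parental exposure flags and person-years.

    Returns ``(cohort, exclusions, exclusion_tally)``.
    """
    if code_map is None:
        code_map = DEFAULT_CODE_MAP
    retained, excluded, tally = apply_adoptee_exclusions(
        persons, links, residency, rules
    )
    phenos = map_phenotypes(diagnoses, code_map)
    all_ids = pd.Index(persons["person_id"].unique(), name="person_id")
    phenos = phenos.reindex(all_ids)
    for pheno in code_map:
        phenos[pheno] = phenos[pheno].eq(True)

    cohort = retained.set_index("person_id").join(phenos)
    links_retained = links[links["adoptee_id"].isin(cohort.index)]
    exposure = classify_exposure(links_retained, phenos)
    cohort = cohort.join(exposure)
    for col in ("exposure_bio", "exposure_adopt"):
        cohort[col] = cohort[col].eq(True)

    end = pd.concat(
        [
            cohort["tinnitus_first_date"],
            cohort["death_date"],
            cohort["emigration_date"],
            pd.Series(pd.Timestamp(study_end), index=cohort.index),
        ],
        axis=1,
    ).min(axis=1)
    if (end < cohort["birth_date"]).any():
        raise ValueError("corrupt dates: follow-up ends before birth")
    cohort["person_years"] = (
        (end - cohort["birth_date"]).dt.days / DAYS_PER_YEAR
    )
    cohort["birth_year"] = cohort["birth_date"].dt.year
    return cohort.reset_index(), excluded, tally
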