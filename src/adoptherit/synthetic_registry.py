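"""Synthetic adoption-registry generator under a liability-threshold model.

Each family consists of two biological parents, two adoptive parents and
one adoptee.  Liabilities are standard normal with variance partitioned
into additive genetics (``h2``), adoptive-household shared environment
(``c2``) and an independent residual:

* biological parent:  ``L = A + E``, ``A ~ N(0, h2)``, ``E ~ N(0, 1-h2)``
* adoptee:            ``A = (A_mother + A_father)/2 + N(0, h2/2)``
  (Mendelian segregation deviation, so offspring additive variance is
  again ``h2``), plus the household ``C ~ N(0, c2)`` and
  ``E ~ N(0, 1-h2-c2)``
* adoptive parent:    own independent ``A ~ N(0, h2)`` plus the same
  household ``C`` and ``E ~ N(0, 1-h2-c2)``

which yields ``Cov(adoptee, biological parent) = h2/2`` and
``Cov(adoptee, adoptive parent) = c2`` with unit variances.  A person is
affected iff liability exceeds the threshold set by the prevalence.
Parents are drawn independently (no assortative mating).

On top of the trait model the generator emits registry-shaped tables:
birth/death/emigration dates, counties, education, diagnosis records with
era-appropriate ICD revisions, comorbidity flags drawn with a simple
log-odds bump for affected persons, and residency rows used by the
cohabitation exclusion.  The censoring process (death and emigration
hazards, diagnosis-age distributions) is synthetic-only plumbing: it is
calibrated loosely to the study population's demography, not estimated
from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .liability import liability_threshold
from .registry_model import DEFAULT_CODE_MAP

__all__ = [
    "SimulationConfig",
    "FamilyDraws",
    "RegistryTables",
    "simulate_families",
    "generate_registry",
    "SYNTHETIC_CODE_MAP",
]

#: Code map covering the synthetic comorbidity records (ICD-10 only) in
#: addition to the cross-revision tinnitus map.
SYNTHETIC_CODE_MAP: dict[str, list[tuple[int, str]]] = {
    **DEFAULT_CODE_MAP,
    "depression": [(10, "F32")],
    "anxiety": [(10, "F41")],
    "hearing_loss": [(10, "H90")],
}


@dataclass
class SimulationConfig:
    """Generator settings; the seed fully determines the output."""

    n_adoptees: int = 11_060
    h2: float = 0.32
    c2: float = 0.0
    prevalence: float = 0.02
    seed: int = 1

    # demographics
    adoptee_birth_years: tuple[int, int] = (1960, 1990)
    bio_parent_age_at_birth: tuple[float, float] = (24.0, 5.0)
    adoptive_parent_age_at_birth: tuple[float, float] = (33.0, 6.0)
    n_counties: int = 24
    n_areas: int = 2000
    p_female_adoptee: float = 0.4713
    education_probs: dict[str, float] = field(
        default_factory=lambda: {
            "low": 0.30, "middle": 0.35, "high": 0.25, "unknown": 0.10,
        }
    )

    # diagnosis-age model: role -> (median, sd), Normal truncated [16, 90]
    diagnosis_age: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "adoptee": (43.0, 7.0),
            "biological_parent": (65.0, 7.5),
            "adoptive_parent": (71.0, 10.0),
        }
    )
    diagnosis_age_bounds: tuple[float, float] = (16.0, 90.0)

    # censoring (synthetic-only free parameters)
    p_child_death: float = 0.003
    death_age: tuple[float, float] = (80.0, 10.0)
    p_emigrate: float = 0.02
    emigration_age_range: tuple[float, float] = (1.0, 60.0)

    # registry imperfections
    p_cohabit: float = 0.01
    cohabit_years: int = 3
    p_missing_bio_link: float = 0.005

    # comorbidities: name -> (baseline rate, log-odds bump when the person
    # has tinnitus); realism only, no causal structure
    comorbidities: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "depression": (0.15, 0.7),
            "anxiety": (0.20, 0.8),
            "hearing_loss": (0.05, 2.5),
        }
    )
    comorbidity_age: tuple[float, float] = (50.0, 15.0)

    study_end_year: int = 2015

    def validate(self) -> None:
        if self.n_adoptees < 0:
            raise ValueError("n_adoptees must be non-negative")
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must be in [0, 1]")
        if not 0.0 <= self.c2 < 1.0:
            raise ValueError("c2 must be in [0, 1)")
        if self.h2 + self.c2 > 1.0:
            raise ValueError("h2 + c2 must not exceed 1")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must be in (0, 1)")
        probs = np.array(list(self.education_probs.values()))
        if abs(probs.sum() - 1.0) > 1e-9:
            raise ValueError("education_probs must sum to 1")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        cfg = cls(**raw)
        # YAML lists arrive as lists; normalise the pair-valued fields
        for name in (
            "adoptee_birth_years", "bio_parent_age_at_birth",
            "adoptive_parent_age_at_birth", "diagnosis_age_bounds",
            "death_age", "emigration_age_range", "comorbidity_age",
        ):
            setattr(cfg, name, tuple(getattr(cfg, name)))
        cfg.diagnosis_age = {
            k: tuple(v) for k, v in cfg.diagnosis_age.items()
        }
        cfg.comorbidities = {
            k: tuple(v) for k, v in cfg.comorbidities.items()
        }
        cfg.validate()
        return cfg

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self)))


MEMBERS = (
    "bio_mother", "bio_father", "adoptive_mother", "adoptive_father",
    "adoptee",
)


@dataclass
class FamilyDraws:
    """Latent liabilities and affection statuses, one entry per family."""

    threshold: float
    liability: dict[str, np.ndarray]
    affected: dict[str, np.ndarray]
    additive: dict[str, np.ndarray]
    household: np.ndarray

    @property
    def n(self) -> int:
        return len(self.household)


def simulate_families(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> FamilyDraws:
    """Draw per-family liabilities and affection statuses."""
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_adoptees
    h2, c2 = config.h2, config.c2
    res_parent = 1.0 - h2
    res_house = 1.0 - h2 - c2

    a = {
        m: rng.normal(0.0, np.sqrt(h2), n)
        for m in ("bio_mother", "bio_father", "adoptive_mother",
                  "adoptive_father")
    }
    a["adoptee"] = (
        0.5 * (a["bio_mother"] + a["bio_father"])
        + rng.normal(0.0, np.sqrt(h2 / 2.0), n)
    )
    c = rng.normal(0.0, np.sqrt(c2), n)

    liab = {}
    for m in ("bio_mother", "bio_father"):
        liab[m] = a[m] + rng.normal(0.0, np.sqrt(res_parent), n)
    for m in ("adoptive_mother", "adoptive_father", "adoptee"):
        liab[m] = a[m] + c + rng.normal(0.0, np.sqrt(res_house), n)

    t = liability_threshold(config.prevalence)
    affected = {m: liab[m] > t for m in MEMBERS}
    return FamilyDraws(
        threshold=t, liability=liab, affected=affected, additive=a,
        household=c,
    )


@dataclass
class RegistryTables:
    persons: pd.DataFrame
    links: pd.DataFrame
    diagnoses: pd.DataFrame
    residency: pd.DataFrame

    def write(self, out_dir: str | Path) -> dict[str, Path]:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name in ("persons", "links", "diagnoses", "residency"):
            df = getattr(self, name).copy()
            for col in df.columns:
                if pd.api.types.is_datetime64_any_dtype(df[col]):
                    df[col] = df[col].dt.strftime("%Y-%m-%d")
            paths[name] = out / f"{name}.csv"
            df.to_csv(paths[name], index=False)
        return paths


def _dates_from_year(
    rng: np.random.Generator, years: np.ndarray
) -> pd.Series:
    day = rng.integers(0, 365, len(years))
    base = pd.to_datetime(
        pd.DataFrame({"year": years, "month": 1, "day": 1})
    )
    return base + pd.to_timedelta(day, unit="D")


def _truncnorm(
    rng: np.random.Generator,
    mean: float,
    sd: float,
    lo: float,
    hi: float,
    size: int,
) -> np.ndarray:
    # rejection sampling; the truncation regions used here keep the
    # acceptance rate high
    out = rng.normal(mean, sd, size)
    bad = (out < lo) | (out > hi)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out < lo) | (out > hi)
    return out


def _icd_for_year(year: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    version = np.select(
        [year >= 1997, year >= 1987, year >= 1969],
        [10, 9, 8],
        default=7,
    )
    code = np.select(
        [version == 10, version == 9, version == 8],
        ["H931", "388D", "781.31"],
        default="781.32",
    )
    return version, code


def generate_registry(
    config: SimulationConfig,
    draws: FamilyDraws | None = None,
) -> RegistryTables:
    """Materialise a family draw as the four registry tables.

    Deterministic under ``config.seed``: the same config yields
    byte-identical files.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    if draws is None:
        draws = simulate_families(config, rng)
    n = draws.n
    end_ts = pd.Timestamp(year=config.study_end_year, month=12, day=31)

    ids = {
        "adoptee": np.array([f"AD{i:06d}" for i in range(n)]),
        "bio_mother": np.array([f"BM{i:06d}" for i in range(n)]),
        "bio_father": np.array([f"BF{i:06d}" for i in range(n)]),
        "adoptive_mother": np.array([f"AM{i:06d}" for i in range(n)]),
        "adoptive_father": np.array([f"AF{i:06d}" for i in range(n)]),
    }
    role_of = {
        "adoptee": "adoptee",
        "bio_mother": "biological_parent",
        "bio_father": "biological_parent",
        "adoptive_mother": "adoptive_parent",
        "adoptive_father": "adoptive_parent",
    }
    sex_of = {
        "bio_mother": "female", "bio_father": "male",
        "adoptive_mother": "female", "adoptive_father": "male",
    }

    lo_y, hi_y = config.adoptee_birth_years
    adoptee_birth_year = rng.integers(lo_y, hi_y + 1, n)
    birth_year = {"adoptee": adoptee_birth_year}
    for member, (mean, sd) in (
        ("bio_mother", config.bio_parent_age_at_birth),
        ("bio_father", config.bio_parent_age_at_birth),
        ("adoptive_mother", config.adoptive_parent_age_at_birth),
        ("adoptive_father", config.adoptive_parent_age_at_birth),
    ):
        age = np.round(_truncnorm(rng, mean, sd, 16.0, 60.0, n))
        birth_year[member] = adoptee_birth_year - age.astype(int)

    birth_date = {
        m: _dates_from_year(rng, birth_year[m]) for m in MEMBERS
    }

    adoptee_sex = np.where(
        rng.random(n) < config.p_female_adoptee, "female", "male"
    )

    edu_levels = list(config.education_probs)
    edu_p = np.array([config.education_probs[k] for k in edu_levels])
    education = {
        m: rng.choice(edu_levels, size=n, p=edu_p) for m in MEMBERS
    }
    county = {
        m: np.char.add(
            "C", rng.integers(1, config.n_counties + 1, n).astype(str)
        )
        for m in MEMBERS
    }

    # censoring
    death_date, emigration_date = {}, {}
    for m in MEMBERS:
        d_age = _truncnorm(
            rng, config.death_age[0], config.death_age[1], 17.0, 105.0, n
        )
        if m == "adoptee" and config.p_child_death > 0:
            child = rng.random(n) < config.p_child_death
            d_age = np.where(child, rng.uniform(0.0, 16.0, n), d_age)
        dd = birth_date[m] + pd.to_timedelta(
            np.round(d_age * 365.25), unit="D"
        )
        death_date[m] = dd.where(dd <= end_ts)
        emig = rng.random(n) < config.p_emigrate
        e_age = rng.uniform(*config.emigration_age_range, n)
        ed = birth_date[m] + pd.to_timedelta(
            np.round(e_age * 365.25), unit="D"
        )
        emigration_date[m] = ed.where(emig & (ed <= end_ts))

    persons = pd.concat(
        [
            pd.DataFrame(
                {
                    "person_id": ids[m],
                    "role": role_of[m],
                    "sex": sex_of.get(m, None) or adoptee_sex,
                    "birth_date": birth_date[m],
                    "death_date": death_date[m],
                    "emigration_date": emigration_date[m],
                    "county_of_birth": county[m],
                    "education": education[m],
                }
            )
            for m in ("adoptee", "bio_mother", "bio_father",
                      "adoptive_mother", "adoptive_father")
        ],
        ignore_index=True,
    )

    # links; a small fraction of adoptees lose both biological links to
    # exercise the missing-link exclusion
    missing = rng.random(n) < config.p_missing_bio_link
    link_frames = []
    for m, kind in (
        ("bio_mother", "biological"),
        ("bio_father", "biological"),
        ("adoptive_mother", "adoptive"),
        ("adoptive_father", "adoptive"),
    ):
        keep = ~missing if kind == "biological" else np.ones(n, bool)
        link_frames.append(
            pd.DataFrame(
                {
                    "adoptee_id": ids["adoptee"][keep],
                    "parent_id": ids[m][keep],
                    "link_kind": kind,
                }
            )
        )
    links = pd.concat(link_frames, ignore_index=True)

    # residency: the adoptive household (incl. adoptee) shares an area,
    # the biological parents share another; rows are year ranges
    house_area = np.char.add(
        "A", rng.integers(0, config.n_areas, n).astype(str)
    )
    bio_area = np.char.add(
        "A", rng.integers(0, config.n_areas, n).astype(str)
    )
    cohabit = rng.random(n) < config.p_cohabit
    res_frames = []
    for m in MEMBERS:
        area = bio_area if m.startswith("bio") else house_area
        start = birth_year[m]
        end_y = np.minimum(
            config.study_end_year,
            np.where(
                death_date[m].notna(),
                death_date[m].dt.year.fillna(config.study_end_year),
                config.study_end_year,
            ),
        ).astype(int)
        if m == "adoptee":
            # cohabiting adoptees spend their first years in the
            # biological household
            res_frames.append(
                pd.DataFrame(
                    {
                        "person_id": ids[m][cohabit],
                        "area_code": bio_area[cohabit],
                        "start_year": birth_year[m][cohabit],
                        "end_year": birth_year[m][cohabit]
                        + config.cohabit_years - 1,
                    }
                )
            )
            start = np.where(
                cohabit, birth_year[m] + config.cohabit_years, start
            )
        res_frames.append(
            pd.DataFrame(
                {
                    "person_id": ids[m],
                    "area_code": area,
                    "start_year": start,
                    "end_year": np.maximum(start, end_y),
                }
            )
        )
    residency = pd.concat(res_frames, ignore_index=True)

    # diagnoses
    censor = {
        m: pd.concat(
            [
                death_date[m],
                emigration_date[m],
                pd.Series(end_ts, index=range(n)),
            ],
            axis=1,
        ).min(axis=1)
        for m in MEMBERS
    }
    dx_frames = []
    lo_a, hi_a = config.diagnosis_age_bounds
    for m in MEMBERS:
        med, sd = config.diagnosis_age[role_of[m]]
        age = _truncnorm(rng, med, sd, lo_a, hi_a, n)
        date = birth_date[m] + pd.to_timedelta(
            np.round(age * 365.25), unit="D"
        )
        ok = (
            draws.affected[m]
            & (date <= censor[m]).to_numpy()
            & (date.dt.year >= 1964).to_numpy()
        )
        year = date.dt.year.to_numpy()[ok]
        version, code = _icd_for_year(year)
        u = rng.random(n)[ok]
        source = np.select(
            [year >= 2001, year >= 1997],
            [
                np.select(
                    [u < 0.51, u < 0.98],
                    ["outpatient", "primary_care"],
                    default="hospital_discharge",
                ),
                np.where(u < 0.7, "primary_care", "hospital_discharge"),
            ],
            default="hospital_discharge",
        )
        dx_frames.append(
            pd.DataFrame(
                {
                    "person_id": ids[m][ok],
                    "icd_version": version,
                    "code": code,
                    "diagnosis_date": date[ok],
                    "source": source,
                }
            )
        )
    # comorbidities (ICD-10 era records only)
    comorbidity_codes = {
        name: SYNTHETIC_CODE_MAP[name][0]
        for name in config.comorbidities
        if name in SYNTHETIC_CODE_MAP
    }
    for name, (base, bump) in config.comorbidities.items():
        version10, code10 = comorbidity_codes.get(name, (10, name))
        logit = np.log(base / (1.0 - base))
        for m in MEMBERS:
            p = 1.0 / (
                1.0 + np.exp(-(logit + bump * draws.affected[m]))
            )
            has = rng.random(n) < p
            age = _truncnorm(
                rng, config.comorbidity_age[0], config.comorbidity_age[1],
                lo_a, hi_a, n,
            )
            date = birth_date[m] + pd.to_timedelta(
                np.round(age * 365.25), unit="D"
            )
            ok = (
                has
                & (date <= censor[m]).to_numpy()
                & (date.dt.year >= 1997).to_numpy()
            )
            dx_frames.append(
                pd.DataFrame(
                    {
                        "person_id": ids[m][ok],
                        "icd_version": version10,
                        "code": code10,
                        "diagnosis_date": date[ok],
                        "source": np.where(
                            date.dt.year.to_numpy()[ok] >= 2001,
                            "outpatient", "primary_care",
                        ),
                    }
                )
            )
    diagnoses = (
        pd.concat(dx_frames, ignore_index=True)
        if dx_frames
        else pd.DataFrame(
            columns=["person_id", "icd_version", "code", "diagnosis_date",
                     "source"]
        )
    )
    if len(diagnoses):
        diagnoses = diagnoses.sort_values(
            ["person_id", "diagnosis_date", "code"], kind="mergesort"
        ).reset_index(drop=True)

    return RegistryTables(
        persons=persons, links=links, diagnoses=diagnoses,
        residency=residency,
    )
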