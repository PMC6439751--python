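"""1:4 matched case-control sampling of adoptees and conditional
logistic estimation of the parental-exposure odds ratios.

Cases are tinnitus-affected adoptees; controls are tinnitus-unaffected
adoptees matched exactly on sex, educational attainment and county of
birth, with birth year within a +/-1 year caliper.  Controls are sampled
without replacement across sets, so the conditional likelihood factors
independently over sets.  Cases that cannot be given a full complement of
controls are set aside and reported rather than matched at a reduced
ratio.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from statsmodels.discrete.conditional_models import ConditionalLogit

__all__ = [
    "MatchCriteria",
    "MatchResult",
    "ConditionalLogitFit",
    "match_controls",
    "fit_conditional_logistic",
]

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class MatchCriteria:
    exact: tuple[str, ...] = ("sex", "education", "county_of_birth")
    caliper_var: str = "birth_year"
    caliper: float = 1.0
    ratio: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ratio < 1:
            raise ValueError("ratio must be >= 1")


@dataclass
class MatchResult:
    """Long-format matched sets plus the cases left unmatched.

    ``sets`` has one row per member with columns ``set_id, person_id,
    is_case`` plus the matching variables carried over.
    """

    sets: pd.DataFrame
    unmatched_cases: list[str] = field(default_factory=list)

    @property
    def n_sets(self) -> int:
        return self.sets["set_id"].nunique() if len(self.sets) else 0


def match_controls(
    cases: pd.DataFrame,
    pool: pd.DataFrame,
    criteria: MatchCriteria | None = None,
) -> MatchResult:
    """Greedy 1:ratio matching, deterministic under the criteria seed.

    Cases are processed in a seeded random order; for each case the
    eligible, still-unused controls are sampled without replacement.  A
    case with fewer than ``ratio`` eligible controls is recorded as
    unmatched.
    """
    if criteria is None:
        criteria = MatchCriteria()
    overlap = set(cases["person_id"]) & set(pool["person_id"])
    if overlap:
        raise ValueError(
            f"case and control pools overlap on {len(overlap)} person(s)"
        )
    rng = np.random.default_rng(criteria.seed)
    if pool.empty:
        warnings.warn("control pool is empty; every case is unmatched",
                      stacklevel=2)
        return MatchResult(
            sets=pd.DataFrame(
                columns=["set_id", "person_id", "is_case"]
            ),
            unmatched_cases=sorted(cases["person_id"].tolist()),
        )

    pool = pool.sort_values("person_id").reset_index(drop=True)
    key_cols = list(criteria.exact)
    grouped: dict[tuple, pd.DataFrame] = {
        key: sub for key, sub in pool.groupby(key_cols, sort=True)
    }
    used: set[str] = set()
    case_order = cases.sort_values("person_id").reset_index(drop=True)
    case_order = case_order.iloc[rng.permutation(len(case_order))]

    rows = []
    unmatched = []
    set_id = 0
    carry = [c for c in cases.columns if c != "person_id"]
    for _, case in case_order.iterrows():
        key = tuple(case[c] for c in key_cols)
        sub = grouped.get(key if len(key_cols) > 1 else key[0])
        if sub is None:
            unmatched.append(case["person_id"])
            continue
        ok = sub[
            (sub[criteria.caliper_var] - case[criteria.caliper_var]).abs()
            <= criteria.caliper
        ]
        ok = ok[~ok["person_id"].isin(used)]
        if len(ok) < criteria.ratio:
            unmatched.append(case["person_id"])
            continue
        pick = ok.iloc[
            rng.choice(len(ok), size=criteria.ratio, replace=False)
        ]
        used.update(pick["person_id"])
        rows.append(
            {"set_id": set_id, "person_id": case["person_id"],
             "is_case": True, **{c: case[c] for c in carry}}
        )
        for _, ctrl in pick.iterrows():
            rows.append(
                {"set_id": set_id, "person_id": ctrl["person_id"],
                 "is_case": False,
                 **{c: ctrl[c] for c in carry if c in ctrl.index}}
            )
        set_id += 1
    sets = (
        pd.DataFrame(rows)
        if rows
        else pd.DataFrame(columns=["set_id", "person_id", "is_case"])
    )
    return MatchResult(sets=sets, unmatched_cases=sorted(unmatched))


@dataclass(frozen=True)
class ConditionalLogitFit:
    beta: float
    se: float
    odds_ratio: float
    ci_low: float
    ci_high: float
    n_sets: int
    n_informative: int
    converged: bool


def fit_conditional_logistic(
    sets: pd.DataFrame, exposure: str
) -> ConditionalLogitFit:
    """Conditional logistic regression of case status on a binary
    exposure within matched sets.

    Maximizes the likelihood ``prod_i exp(x_case b) / sum_j exp(x_j b)``
    over sets ``i``.  Sets with no within-set exposure variation carry no
    information and are dropped before fitting; if none remain the data
    cannot identify the OR and an error is raised.
    """
    if not len(sets):
        raise ValueError("no matched sets supplied")
    x = sets[exposure].astype(bool).astype(float)
    informative = (
        x.groupby(sets["set_id"]).transform("nunique") > 1
    )
    n_sets = sets["set_id"].nunique()
    n_informative = int(
        sets.loc[informative, "set_id"].nunique()
    )
    if n_informative == 0:
        raise ValueError(
            "all matched sets are exposure-concordant; the conditional "
            "likelihood carries no information"
        )
    sub = sets[informative]
    model = ConditionalLogit(
        sub["is_case"].astype(int).to_numpy(),
        sub[[exposure]].astype(float).to_numpy(),
        groups=sub["set_id"].to_numpy(),
    )
    res = model.fit(disp=0)
    beta = float(res.params[0])
    se = float(res.bse[0])
    try:
        converged = bool(res.mle_retvals.get("converged", True))
    except AttributeError:
        # ConditionalLogit results do not expose optimizer diagnostics;
        # a finite, non-degenerate SE is the usable convergence signal
        converged = bool(np.isfinite(res.params[0]) and np.isfinite(res.bse[0]))
    return ConditionalLogitFit(
        beta=beta,
        se=se,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - _Z95 * se)),
        ci_high=float(np.exp(beta + _Z95 * se)),
        n_sets=n_sets,
        n_informative=n_informative,
        converged=converged,
    )
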