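"""Cohort-level association statistics: incidence rates and ratios by
parental exposure, crude and multivariable logistic odds ratios, and 2x2
table statistics for comorbidities.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

__all__ = [
    "IncidenceResult",
    "RateRatioResult",
    "TwoByTwoTable",
    "TwoByTwoStats",
    "LogisticFit",
    "SeparationError",
    "incidence_rate",
    "rate_ratio",
    "two_by_two_stats",
    "fit_logistic",
    "exposure_table",
    "incidence_by_exposure",
]

_Z95 = 1.959963984540054

#: Upper 95% bound on the event count when zero events are observed
#: (rule of three on the exact Poisson scale: -ln 0.025).
_RULE_OF_THREE = 3.688879454113936


@dataclass(frozen=True)
class IncidenceResult:
    events: int
    person_years: float
    rate_per_1000: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class RateRatioResult:
    ratio: float
    ci_low: float
    ci_high: float


@dataclass(frozen=True)
class TwoByTwoTable:
    """Counts: a exposed-case, b exposed-noncase, c unexposed-case,
    d unexposed-noncase."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise ValueError("2x2 counts must be non-negative")


@dataclass(frozen=True)
class TwoByTwoStats:
    odds_ratio: float
    ci_low: float
    ci_high: float
    chi2: float
    p_value: float
    continuity_corrected: bool = False


@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS) with Wald inference."""

    params: pd.Series
    bse: pd.Series
    odds_ratios: pd.DataFrame  # columns: or, ci_low, ci_high
    converged: bool
    n_iter: int
    n_obs: int


class SeparationError(RuntimeError):
    """The likelihood is unbounded (complete separation or a degenerate
    outcome); no finite estimates exist."""


def incidence_rate(events: int, person_years: float) -> IncidenceResult:
    """Events per 1000 person-years with a log-scale Wald 95% CI,
    ``exp(ln rate +/- 1.96/sqrt(events))``.

    With zero events the rate is 0 and the upper bound uses the
    rule-of-three Poisson limit ``1000 * 3.69 / person_years``.
    """
    if person_years <= 0:
        raise ValueError("person_years must be positive")
    if events < 0:
        raise ValueError("events must be non-negative")
    if events == 0:
        return IncidenceResult(
            0, person_years, 0.0, 0.0,
            1000.0 * _RULE_OF_THREE / person_years,
        )
    rate = 1000.0 * events / person_years
    half = _Z95 / math.sqrt(events)
    return IncidenceResult(
        events, person_years, rate,
        rate * math.exp(-half), rate * math.exp(half),
    )


def rate_ratio(
    exposed: IncidenceResult, unexposed: IncidenceResult
) -> RateRatioResult:
    """Incidence rate ratio with log-normal 95% CI
    ``exp(ln ratio +/- 1.96 * sqrt(1/e1 + 1/e0))``."""
    if exposed.events == 0 or unexposed.events == 0:
        raise ValueError(
            "zero events in an arm; use exact (Poisson) methods instead"
        )
    ratio = exposed.rate_per_1000 / unexposed.rate_per_1000
    half = _Z95 * math.sqrt(1.0 / exposed.events + 1.0 / unexposed.events)
    return RateRatioResult(
        ratio, ratio * math.exp(-half), ratio * math.exp(half)
    )


def two_by_two_stats(table: TwoByTwoTable) -> TwoByTwoStats:
    """Cross-product odds ratio with Woolf 95% CI and the Pearson
    chi-square (1 df, no continuity correction).

    Zero cells trigger a documented 0.5 continuity correction for the OR
    (with a warning); a zero margin is an error.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    corrected = False
    if min(a, b, c, d) == 0:
        warnings.warn(
            "zero cell in 2x2 table; applying 0.5 continuity correction "
            "to the odds ratio",
            stacklevel=2,
        )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        corrected = True
    orr = (a * d) / (b * c)
    se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    chi2, p, _, _ = stats.chi2_contingency(
        [[table.a, table.b], [table.c, table.d]], correction=False
    )
    return TwoByTwoStats(
        odds_ratio=orr,
        ci_low=orr * math.exp(-_Z95 * se_log),
        ci_high=orr * math.exp(_Z95 * se_log),
        chi2=float(chi2),
        p_value=float(p),
        continuity_corrected=corrected,
    )


def _expand_design(X: pd.DataFrame) -> pd.DataFrame:
    """Indicator-expand non-numeric covariates (reference = first level)
    and prepend an intercept."""
    cat_cols = [
        c for c in X.columns
        if not pd.api.types.is_numeric_dtype(X[c])
        or isinstance(X[c].dtype, pd.CategoricalDtype)
    ]
    design = pd.get_dummies(
        X, columns=cat_cols, drop_first=True, dtype=float
    )
    design = design.astype(float)
    return sm.add_constant(design, has_constant="add")


def fit_logistic(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Logistic regression by Newton-Raphson (IRLS) with Wald standard
    errors from the inverse observed information.

    The intercept is added automatically and categorical covariates are
    expanded to indicators against their first level.  A constant outcome
    or complete separation raises :class:`SeparationError`; plain
    non-convergence is reported via the ``converged`` flag with no
    estimates interpreted.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("outcome must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise SeparationError("outcome is constant; model is degenerate")
    design = _expand_design(X)
    with warnings.catch_warnings():
        warnings.simplefilter("error", sm.tools.sm_exceptions.PerfectSeparationWarning)
        try:
            res = sm.Logit(y, design).fit(
                method="newton", maxiter=max_iter, tol=tol, disp=0,
                warn_convergence=False,
            )
        except (
            sm.tools.sm_exceptions.PerfectSeparationError,
            sm.tools.sm_exceptions.PerfectSeparationWarning,
            np.linalg.LinAlgError,
        ) as err:
            raise SeparationError(
                f"logistic likelihood is degenerate: {err}"
            ) from err
    converged = bool(res.mle_retvals.get("converged", False))
    ors = pd.DataFrame(
        {
            "or": np.exp(res.params),
            "ci_low": np.exp(res.params - _Z95 * res.bse),
            "ci_high": np.exp(res.params + _Z95 * res.bse),
        }
    )
    return LogisticFit(
        params=res.params,
        bse=res.bse,
        odds_ratios=ors,
        converged=converged,
        n_iter=int(res.mle_retvals.get("iterations", 0)),
        n_obs=len(y),
    )


def exposure_table(
    cohort: pd.DataFrame, exposure: str, outcome: str = "tinnitus"
) -> TwoByTwoTable:
    e = cohort[exposure].astype(bool)
    o = cohort[outcome].astype(bool)
    return TwoByTwoTable(
        a=int((e & o).sum()),
        b=int((e & ~o).sum()),
        c=int((~e & o).sum()),
        d=int((~e & ~o).sum()),
    )


MODEL2_COVARIATES = (
    "birth_year", "sex", "county_of_birth", "education",
    "depression", "anxiety", "hearing_loss",
)


def incidence_by_exposure(
    cohort: pd.DataFrame,
    exposure: str,
    outcome: str = "tinnitus",
    adjust: tuple[str, ...] = MODEL2_COVARIATES,
) -> pd.DataFrame:
    """One exposure block of the cohort table: incidence rates per arm,
    the rate ratio, and crude (model 1) / adjusted (model 2) logistic ORs.

    Model 2 adjusts for whichever of ``adjust`` are present as columns;
    birth year enters continuously, county and education as unordered
    categoricals.  An arm with zero events (or a degenerate likelihood)
    yields NaN ratio/OR fields rather than an error, so sparse cohorts
    still produce a report.
    """
    rows = []
    arms = {}
    for flag, label in ((False, "unexposed"), (True, "exposed")):
        sub = cohort[cohort[exposure].astype(bool) == flag]
        arms[label] = incidence_rate(
            int(sub[outcome].astype(bool).sum()),
            float(sub["person_years"].sum()),
        )
    try:
        rr = rate_ratio(arms["exposed"], arms["unexposed"])
    except ValueError:
        rr = RateRatioResult(float("nan"), float("nan"), float("nan"))

    nan_or = pd.DataFrame(
        {"or": float("nan"), "ci_low": float("nan"),
         "ci_high": float("nan")}, index=[exposure],
    )
    y = cohort[outcome].astype(bool).astype(int)
    x1 = cohort[[exposure]].astype(float)
    present = [c for c in adjust if c in cohort.columns]
    x2 = cohort[[exposure] + present].copy()
    for c in [exposure, "depression", "anxiety", "hearing_loss"]:
        if c in x2.columns:
            x2[c] = x2[c].astype(bool).astype(float)
    fits = []
    for design in (x1, x2):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                fit = fit_logistic(design, y)
            fits.append(fit.odds_ratios if fit.converged else nan_or)
        except SeparationError:
            fits.append(nan_or)
    m1, m2 = fits

    for label in ("unexposed", "exposed"):
        inc = arms[label]
        row = {
            "arm": label,
            "events": inc.events,
            "persons": int(
                (cohort[exposure].astype(bool) == (label == "exposed")).sum()
            ),
            "person_years": inc.person_years,
            "rate_per_1000": inc.rate_per_1000,
            "rate_ci_low": inc.ci_low,
            "rate_ci_high": inc.ci_high,
        }
        if label == "exposed":
            row.update(
                rate_ratio=rr.ratio,
                rate_ratio_ci_low=rr.ci_low,
                rate_ratio_ci_high=rr.ci_high,
                or_model1=m1.loc[exposure, "or"],
                or_model1_ci_low=m1.loc[exposure, "ci_low"],
                or_model1_ci_high=m1.loc[exposure, "ci_high"],
                or_model2=m2.loc[exposure, "or"],
                or_model2_ci_low=m2.loc[exposure, "ci_low"],
                or_model2_ci_high=m2.loc[exposure, "ci_high"],
            )
        rows.append(row)
    return pd.DataFrame(rows)
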