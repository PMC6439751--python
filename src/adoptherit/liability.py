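"""Liability-threshold heritability machinery.

A binary trait is modelled as the dichotomization of an unobserved
standard-normal liability: a person is affected iff their liability exceeds
the threshold implied by the trait's prevalence.  The familial resemblance
of a relative pair is then the correlation of the underlying bivariate
normal (the *tetrachoric* correlation), and for a pair with additive
genetic correlation ``relatedness`` (0.5 for parent-offspring) with no
shared environment, heritability is ``h2 = r / relatedness``.

Two estimators are provided:

* the tetrachoric route: solve the liability correlation from an observed
  odds ratio plus assumed margin prevalences (usable directly on a
  published case-control OR), with a delta-method standard error
  propagated from the log-OR scale;
* Falconer regression: compare trait prevalence among relatives of
  probands (``q_r``) vs relatives of controls (``q_g``) through normal
  thresholds ``x`` and the mean liability of affected individuals
  ``a = phi(x)/q``, giving ``b = (x_g - x_r)/a_g`` and ``h2 = b/relatedness``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import integrate, optimize, special, stats

__all__ = [
    "DEFAULT_PREVALENCES",
    "TetrachoricResult",
    "FalconerInputs",
    "HeritabilityEstimate",
    "liability_threshold",
    "bvn_upper_tail",
    "or_from_tetrachoric",
    "tetrachoric_from_or",
    "tetrachoric_from_counts",
    "se_log_or_from_ci",
    "se_tetrachoric",
    "heritability_from_correlation",
    "falconer_heritability",
    "sensitivity_table",
]

#: Assumed-prevalence grid for the sensitivity analysis (proportions).
DEFAULT_PREVALENCES: tuple[float, ...] = (
    0.0001, 0.0005, 0.001, 0.005, 0.01, 0.02, 0.05,
)


@dataclass(frozen=True)
class TetrachoricResult:
    """Tetrachoric correlation solved from an odds ratio."""

    r: float
    se_r: float | None
    prevalence_assumed: float
    or_input: float
    threshold: float
    #: prevalence used for the second (relative/exposure) margin
    exposure_prevalence: float | None = None


@dataclass(frozen=True)
class FalconerInputs:
    """Inputs to Falconer regression.

    ``q_g``: trait prevalence among relatives of controls (the general
    comparison group); ``q_r``: prevalence among relatives of probands;
    ``n_g``/``n_r``: relative counts behind those proportions (for the
    binomial SE); ``relatedness``: additive genetic correlation of the
    relative pair (0.5 for parent-offspring).
    """

    q_g: float
    q_r: float
    n_g: int | None = None
    n_r: int | None = None
    relatedness: float = 0.5

    def __post_init__(self) -> None:
        for name in ("q_g", "q_r"):
            q = getattr(self, name)
            if not 0.0 < q < 1.0:
                raise ValueError(f"{name} must be in (0, 1), got {q}")
        if not 0.0 < self.relatedness <= 1.0:
            raise ValueError("relatedness must be in (0, 1]")


@dataclass(frozen=True)
class HeritabilityEstimate:
    """Heritability on the liability scale, clipped to [0, 1]."""

    h2: float
    se_h2: float | None
    method: str
    relatedness: float
    #: True when the raw estimate fell outside [0, 1] before clipping.
    out_of_range: bool = False
    raw_h2: float = field(default=float("nan"))


def liability_threshold(prevalence: float) -> float:
    """Standard-normal threshold above which a trait with the given
    prevalence is expressed: ``t = Phi^{-1}(1 - prevalence)``."""
    if not 0.0 < prevalence < 1.0:
        raise ValueError(f"prevalence must be in (0, 1), got {prevalence}")
    return float(stats.norm.isf(prevalence))


def _bvn_cdf_quad(h: float, k: float, rho: float) -> float:
    # Drezner-Wesolowsky correlation integral; exact at rho=0, robust at
    # zero thresholds where the Owen route degenerates.
    base = stats.norm.cdf(h) * stats.norm.cdf(k)

    def integrand(r: float) -> float:
        return math.exp(
            -(h * h - 2.0 * r * h * k + k * k) / (2.0 * (1.0 - r * r))
        ) / math.sqrt(1.0 - r * r)

    val, _ = integrate.quad(integrand, 0.0, rho, epsabs=1e-13, epsrel=1e-12)
    return base + val / (2.0 * math.pi)


def _bvn_cdf(h: float, k: float, rho: float) -> float:
    """P(X <= h, Y <= k) for standard bivariate normal, via Owen's T."""
    if rho == 0.0:
        return float(stats.norm.cdf(h) * stats.norm.cdf(k))
    if abs(h) < 1e-12 and abs(k) < 1e-12:
        return 0.25 + math.asin(rho) / (2.0 * math.pi)
    if abs(h) < 1e-12 or abs(k) < 1e-12:
        return _bvn_cdf_quad(h, k, rho)
    denom = math.sqrt(1.0 - rho * rho)
    a_h = (k - rho * h) / (h * denom)
    a_k = (h - rho * k) / (k * denom)
    beta = 0.5 if h * k < 0.0 else 0.0
    val = (
        0.5 * (stats.norm.cdf(h) + stats.norm.cdf(k))
        - special.owens_t(h, a_h)
        - special.owens_t(k, a_k)
        - beta
    )
    return float(val)


def bvn_upper_tail(t1: float, t2: float, r: float) -> float:
    """Orthant probability ``P(X > t1, Y > t2)`` under a standard bivariate
    normal with correlation ``r`` (absolute accuracy ~1e-14)."""
    if not abs(r) < 1.0:
        raise ValueError(f"correlation must satisfy |r| < 1, got {r}")
    p = _bvn_cdf(-t1, -t2, r)
    return float(min(1.0, max(0.0, p)))


def _cell_probabilities(
    p1: float, p2: float, r: float
) -> tuple[float, float, float, float]:
    t1 = liability_threshold(p1)
    t2 = liability_threshold(p2)
    p11 = bvn_upper_tail(t1, t2, r)
    p10 = p1 - p11
    p01 = p2 - p11
    p00 = 1.0 - p1 - p2 + p11
    return p11, p10, p01, p00


def or_from_tetrachoric(
    prevalence: float, r: float, exposure_prevalence: float | None = None
) -> float:
    """Odds ratio of the 2x2 table implied by dichotomizing a bivariate
    normal with correlation ``r`` at the margin prevalences.

    By default both margins use ``prevalence``; pass ``exposure_prevalence``
    for an asymmetric table (e.g. the proband margin at an assumed
    population prevalence and the relative/exposure margin at its observed
    rate).
    """
    p2 = prevalence if exposure_prevalence is None else exposure_prevalence
    if not 0.0 < p2 < 1.0:
        raise ValueError("exposure_prevalence must be in (0, 1)")
    p11, p10, p01, p00 = _cell_probabilities(prevalence, p2, r)
    if min(p11, p10, p01, p00) <= 0.0:
        raise ValueError(
            "degenerate implied 2x2 table (a cell probability is zero)"
        )
    return p11 * p00 / (p10 * p01)


_R_BRACKET = 0.999999


def tetrachoric_from_or(
    prevalence: float,
    or_obs: float,
    exposure_prevalence: float | None = None,
    se_log_or: float | None = None,
) -> TetrachoricResult:
    """Solve the tetrachoric correlation whose implied 2x2 table has the
    observed odds ratio, by bracketed root finding (unique by monotonicity
    of the OR in ``r``)."""
    if or_obs <= 0.0:
        raise ValueError(f"odds ratio must be positive, got {or_obs}")
    t = liability_threshold(prevalence)
    if or_obs == 1.0:
        r = 0.0
    else:
        p2 = prevalence if exposure_prevalence is None else exposure_prevalence
        log_target = math.log(or_obs)

        def objective(rr: float) -> float:
            # near |r|=1 the implied table degenerates; the log-OR then
            # diverges with the sign of r, which keeps the bracket valid
            p11, p10, p01, p00 = _cell_probabilities(prevalence, p2, rr)
            if p10 <= 0.0 or p01 <= 0.0:
                return float("inf")
            if p11 <= 0.0 or p00 <= 0.0:
                return float("-inf")
            return math.log(p11 * p00 / (p10 * p01)) - log_target

        r = float(
            optimize.brentq(objective, -_R_BRACKET, _R_BRACKET, xtol=1e-10)
        )
    se_r = (
        None
        if se_log_or is None
        else se_tetrachoric(prevalence, r, se_log_or, exposure_prevalence)
    )
    return TetrachoricResult(
        r=r,
        se_r=se_r,
        prevalence_assumed=prevalence,
        or_input=or_obs,
        threshold=t,
        exposure_prevalence=exposure_prevalence,
    )


def tetrachoric_from_counts(
    a: int, b: int, c: int, d: int
) -> TetrachoricResult:
    """Tetrachoric correlation from raw 2x2 counts.

    Margins set the two thresholds; ``r`` solves the both-affected cell
    probability (two-step estimator).  Cells: ``a`` both affected, ``b``
    first only, ``c`` second only, ``d`` neither.  SE propagates the Woolf
    log-OR variance through the OR-r mapping at the fitted margins.
    """
    if min(a, b, c, d) < 0:
        raise ValueError("counts must be non-negative")
    n = a + b + c + d
    if min(a + b, c + d, a + c, b + d) == 0:
        raise ValueError("a margin of the 2x2 table is zero")
    p1 = (a + b) / n
    p2 = (a + c) / n
    target = a / n
    t1 = liability_threshold(p1)
    t2 = liability_threshold(p2)
    r = float(
        optimize.brentq(
            lambda rr: bvn_upper_tail(t1, t2, rr) - target,
            -_R_BRACKET,
            _R_BRACKET,
            xtol=1e-10,
        )
    )
    se_r = None
    if min(a, b, c, d) > 0:
        se_log = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
        se_r = se_tetrachoric(p1, r, se_log, exposure_prevalence=p2)
    return TetrachoricResult(
        r=r,
        se_r=se_r,
        prevalence_assumed=p1,
        or_input=(a * d) / (b * c) if b * c > 0 else float("inf"),
        threshold=t1,
        exposure_prevalence=p2,
    )


def se_log_or_from_ci(ci_low: float, ci_high: float) -> float:
    """Back-calculate the SE of the log odds ratio from a 95% Wald CI:
    ``(ln hi - ln lo) / (2 * 1.96)``."""
    if not 0.0 < ci_low < ci_high:
        raise ValueError("require 0 < ci_low < ci_high")
    return (math.log(ci_high) - math.log(ci_low)) / (2.0 * 1.959963984540054)


def se_tetrachoric(
    prevalence: float,
    r: float,
    se_log_or: float,
    exposure_prevalence: float | None = None,
) -> float:
    """Delta-method SE of the tetrachoric correlation:
    ``se_r = se_log_or / |d ln OR / d r|`` with the derivative taken by
    central difference (step 1e-5)."""
    if se_log_or < 0.0:
        raise ValueError("se_log_or must be non-negative")
    h = 1e-5
    d = (
        math.log(or_from_tetrachoric(prevalence, r + h, exposure_prevalence))
        - math.log(or_from_tetrachoric(prevalence, r - h, exposure_prevalence))
    ) / (2.0 * h)
    if abs(d) < 1e-12:
        raise ValueError("d ln OR / d r vanishes; SE undefined here")
    return se_log_or / abs(d)


def _clip_h2(raw: float, se: float | None, method: str, relatedness: float
             ) -> HeritabilityEstimate:
    clipped = min(1.0, max(0.0, raw))
    return HeritabilityEstimate(
        h2=clipped,
        se_h2=se,
        method=method,
        relatedness=relatedness,
        out_of_range=not (0.0 <= raw <= 1.0),
        raw_h2=raw,
    )


def heritability_from_correlation(
    r: float, relatedness: float = 0.5, se_r: float | None = None
) -> HeritabilityEstimate:
    """``h2 = r / relatedness`` (adoption design: no shared-environment
    deduction is applied; use the adoptive-parent association to verify
    c2 is negligible)."""
    if relatedness <= 0.0:
        raise ValueError("relatedness must be positive")
    se = None if se_r is None else se_r / relatedness
    return _clip_h2(r / relatedness, se, "tetrachoric_or", relatedness)


def falconer_heritability(inputs: FalconerInputs) -> HeritabilityEstimate:
    """Falconer regression of offspring liability on relative status.

    ``x = Phi^{-1}(1-q)`` per group, ``a_g = phi(x_g)/q_g`` the mean
    liability of affected controls' relatives, ``b = (x_g - x_r)/a_g``,
    ``h2 = b / relatedness``.  SE propagates the binomial variance of each
    prevalence through the threshold transform:
    ``Var(x) = q(1-q) / (n phi(x)^2)``.
    """
    x_g = liability_threshold(inputs.q_g)
    x_r = liability_threshold(inputs.q_r)
    a_g = stats.norm.pdf(x_g) / inputs.q_g
    b = (x_g - x_r) / a_g
    se = None
    if inputs.n_r is not None:
        var_xr = (
            inputs.q_r * (1 - inputs.q_r)
            / (inputs.n_r * stats.norm.pdf(x_r) ** 2)
        )
        var_xg = 0.0
        if inputs.n_g is not None:
            var_xg = (
                inputs.q_g * (1 - inputs.q_g)
                / (inputs.n_g * stats.norm.pdf(x_g) ** 2)
            )
        se = math.sqrt((var_xg + var_xr) / a_g**2) / inputs.relatedness
    return _clip_h2(b / inputs.relatedness, se, "falconer",
                    inputs.relatedness)


def sensitivity_table(
    or_obs: float,
    or_ci: tuple[float, float],
    prevalence_list: tuple[float, ...] = DEFAULT_PREVALENCES,
    relatedness: float = 0.5,
    exposure_prevalence: float | None = None,
) -> pd.DataFrame:
    """Heritability under a grid of assumed population prevalences.

    For each assumed prevalence the observed OR is converted to a
    tetrachoric correlation (margins: assumed prevalence x observed
    exposure prevalence if given), its SE is propagated from the OR's
    95% CI, and heritability follows as ``r / relatedness``.  Returns one
    row per prevalence with columns ``prevalence, r, se_r, h2, se_h2``
    (all proportions).
    """
    if len(prevalence_list) == 0:
        raise ValueError("prevalence_list must be non-empty")
    se_log = se_log_or_from_ci(*or_ci)
    rows = []
    for p in prevalence_list:
        res = tetrachoric_from_or(
            p, or_obs, exposure_prevalence=exposure_prevalence,
            se_log_or=se_log,
        )
        est = heritability_from_correlation(res.r, relatedness, res.se_r)
        rows.append(
            {
                "prevalence": p,
                "r": res.r,
                "se_r": res.se_r,
                "h2": est.h2,
                "se_h2": est.se_h2,
            }
        )
    return pd.DataFrame(rows)
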