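"""Closed-form phase-boundary and survival-probability theory.

The deterministic race between antibiotic killing and enzymatic
degradation has a sharp outcome: a subpopulation at initial density rho
survives iff rho exceeds the critical density

    rho*(a_init) = (gamma / E) * [a_init - a_th + K_M ln(a_init / a_th)],

the ecological phase boundary in the (a_init, rho) plane.  In a habitat
partitioned into m sub-volumes of size v, occupancies are Poisson(rho*v),
so the per-sub-volume survival probability is the upper Poisson tail at
the critical count N* = ceil(rho* v), and the whole-population survival
probability follows from independence: Ps = 1 - (1 - ps)^m.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .params import ModelParams

__all__ = [
    "critical_density",
    "effective_mic",
    "critical_count",
    "subpop_survival_prob",
    "conditional_subpop_survival_prob",
    "total_survival_prob",
    "extreme_fragmentation_survival",
    "occupancy_cv",
    "phase_boundary_table",
    "SurvivalEstimate",
    "EstimateMethod",
    "wilson_interval",
]


class EstimateMethod(enum.Enum):
    ANALYTIC = "ANALYTIC"
    MONTE_CARLO = "MONTE_CARLO"


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion.

    Chosen over the normal approximation because survival probabilities in
    this model routinely sit at 0 or 1, where Wilson remains well behaved.
    """
    from statsmodels.stats.proportion import proportion_confint

    lo, hi = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class SurvivalEstimate:
    """A survival probability with provenance.

    Monte-Carlo estimates carry the replicate count and a Wilson 95%
    confidence interval; analytic values have a degenerate interval.
    ``n_undetermined`` counts replicates whose fate was not resolved
    within the simulation horizon (always 0 for analytic values).
    """

    probability: float
    n_replicates: int
    ci_low: float
    ci_high: float
    method: EstimateMethod
    n_undetermined: int = 0

    def __post_init__(self) -> None:
        if not (0.0 <= self.probability <= 1.0):
            raise ValueError(f"probability out of [0,1]: {self.probability}")
        if not (self.ci_low - 1e-12 <= self.probability <= self.ci_high + 1e-12):
            raise ValueError("probability outside its confidence interval")

    @classmethod
    def analytic(cls, p: float) -> "SurvivalEstimate":
        return cls(p, 0, p, p, EstimateMethod.ANALYTIC)

    @classmethod
    def monte_carlo(
        cls, k: int, n: int, n_undetermined: int = 0
    ) -> "SurvivalEstimate":
        lo, hi = wilson_interval(k, n)
        return cls(k / n, n, lo, hi, EstimateMethod.MONTE_CARLO, n_undetermined)


def critical_density(params: ModelParams, a_init: float) -> float:
    """Critical initial density rho* (cells/ml) for deterministic survival.

    Defined for a_init >= a_th; vanishes at a_init = a_th.  Linear in
    a_init when a_init >> K_M, logarithmic when a_init << K_M.
    """
    if a_init < params.a_th:
        raise ValueError(
            f"a_init={a_init} below a_th={params.a_th}: boundary undefined"
        )
    if params.enzyme_rate == 0.0:
        return math.inf if a_init > params.a_th else 0.0
    bracket = a_init - params.a_th + params.K_M * math.log(a_init / params.a_th)
    return (params.gamma / params.enzyme_rate) * bracket


def effective_mic(params: ModelParams, rho: float) -> float:
    """Largest survivable antibiotic concentration at density rho (ug/ml).

    Inverts the phase boundary: the unique a_init >= a_th with
    rho*(a_init) = rho, found by bracketed root finding (rho* is strictly
    increasing and unbounded in a_init, so the doubling bracket always
    terminates).
    """
    if rho < 0:
        raise ValueError(f"rho must be >= 0, got {rho}")
    if rho == 0.0:
        return params.a_th
    a_lo = params.a_th * (1.0 + 1e-12)
    a_hi = 2.0 * params.a_th
    while critical_density(params, a_hi) < rho:
        a_hi *= 2.0
    return float(
        optimize.brentq(
            lambda a: critical_density(params, a) - rho, a_lo, a_hi, xtol=1e-12, rtol=1e-14
        )
    )


#: relative slack absorbing float fuzz in rho* v before the ceiling
_CEIL_RTOL = 1e-9


def critical_count(params: ModelParams, a_init: float, sub_volume: float) -> int:
    """Critical cell count N* = max(1, ceil(rho* v)) for one sub-volume.

    A tie (rho* v exactly integer, initial count equal to it) counts as
    survival; the ceiling is taken with a small relative slack so that
    float noise in rho* v cannot bump N* past an exact integer.
    """
    if sub_volume <= 0:
        raise ValueError(f"sub_volume must be > 0, got {sub_volume}")
    x = critical_density(params, a_init) * sub_volume
    if math.isinf(x):
        raise OverflowError("critical count is infinite (enzyme_rate = 0)")
    return max(1, math.ceil(x * (1.0 - _CEIL_RTOL)))


def subpop_survival_prob(
    params: ModelParams, a_init: float, rho: float, sub_volume: float
) -> float:
    """Probability that one Poisson-filled sub-volume survives.

    ps = P(X >= N*) with X ~ Poisson(rho * v), evaluated through the
    regularized upper incomplete gamma (scipy's Poisson survival
    function), which is stable for occupancies up to 1e4 and beyond.
    """
    lam = rho * sub_volume
    if lam < 0:
        raise ValueError("negative mean occupancy")
    n_star = critical_count(params, a_init, sub_volume)
    return float(stats.poisson.sf(n_star - 1, lam))


def conditional_subpop_survival_prob(
    params: ModelParams, a_init: float, rho: float, sub_volume: float
) -> float:
    """Survival probability of a sub-volume given it is initially occupied.

    P(X >= N*) / P(X >= 1); equals 1 identically once N* = 1.
    """
    lam = rho * sub_volume
    if lam <= 0:
        raise ValueError("conditional survival requires mean occupancy > 0")
    p_occ = -math.expm1(-lam)
    return subpop_survival_prob(params, a_init, rho, sub_volume) / p_occ


def total_survival_prob(ps: float, m: int) -> float:
    """Whole-population survival: Ps = 1 - (1 - ps)^m.

    Computed via log1p/expm1 so that tiny per-sub-volume probabilities
    amplified by large m do not lose precision.
    """
    if not (0.0 <= ps <= 1.0):
        raise ValueError(f"ps out of [0,1]: {ps}")
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if ps == 1.0:
        return 1.0
    return -math.expm1(m * math.log1p(-ps))


def extreme_fragmentation_survival(rho: float, total_volume: float) -> float:
    """Survival probability in the single-cell-sufficient regime.

    When sub-volumes are so small that one cell exceeds the critical
    density (1/v > rho*), N* = 1 and Ps collapses to the m-independent
    closed form 1 - exp(-rho V): the population survives iff any cell
    exists at all.  Callers are responsible for the regime check.
    """
    if rho < 0 or total_volume <= 0:
        raise ValueError("need rho >= 0 and total_volume > 0")
    return -math.expm1(-rho * total_volume)


def occupancy_cv(rho: float, sub_volume: float) -> float:
    """Coefficient of variation of per-sub-volume density, 1/sqrt(rho v).

    Grows with the degree of partitioning m (lambda = rho V / m), which is
    the stochastic driver of fragmentation rescue.
    """
    lam = rho * sub_volume
    if lam <= 0:
        raise ValueError("occupancy CV requires mean occupancy > 0")
    return 1.0 / math.sqrt(lam)


def phase_boundary_table(params: ModelParams, a_grid) -> "pd.DataFrame":  # noqa: F821
    """Phase boundary rho*(a_init) on a concentration grid, as a DataFrame
    with columns ``a_init_ug_per_ml, rho_star_cells_per_ml``."""
    import pandas as pd

    a_grid = np.asarray(a_grid, dtype=float)
    rho = [critical_density(params, a) for a in a_grid]
    return pd.DataFrame(
        {"a_init_ug_per_ml": a_grid, "rho_star_cells_per_ml": rho}
    )
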