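"""Deterministic dynamics of one subpopulation under threshold-switched
growth/death coupled to Michaelis-Menten antibiotic degradation.

The model: a population of N cells in a well-mixed volume V grows at rate
``mu`` while the antibiotic concentration a(t) is below the threshold a_th
and dies at rate ``gamma`` while it is above; every live cell degrades
antibiotic with Michaelis-Menten kinetics,

    dN/dt = N * [mu * theta(a_th - a) - gamma * theta(a - a_th)]
    da/dt = -(E * N / V) * a / (a + K_M)

with E the per-cell degradation capacity.  Because N(t) is piecewise
exponential, the antibiotic admits an exact implicit solution in terms of
G(a) = a + K_M ln a, and the whole trajectory — including the moment the
concentration crosses the threshold — is available in closed form.  No ODE
stepping is performed anywhere in this module.

The race between exponential killing and degradation yields a sharp
inoculum effect: the population survives iff its initial density exceeds a
critical density rho*(a_init) (see :mod:`fragrescue.theory`).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.special import lambertw

from .params import InitialCondition, ModelParams

__all__ = [
    "Outcome",
    "Trajectory",
    "simulate_deterministic",
    "classify_outcome",
    "antibiotic_crossing_time",
    "advance_antibiotic",
]


class Outcome(enum.Enum):
    """Fate of a subpopulation."""

    SURVIVED = "SURVIVED"
    KILLED = "KILLED"
    UNDETERMINED = "UNDETERMINED"


@dataclass
class Trajectory:
    """Time series of one subpopulation.

    ``pop`` is real-valued for deterministic runs and integer-valued for
    stochastic runs; ``antibiotic`` is the concentration in ug/ml.
    ``t_threshold_crossing`` records when a(t) first reaches a_th from
    above, and is None when the run starts in the growth regime (no
    crossing event exists) or never crosses within the horizon.
    """

    times: np.ndarray
    pop: np.ndarray
    antibiotic: np.ndarray
    outcome: Outcome
    t_threshold_crossing: Optional[float] = None
    #: stochastic runs only: (t_min, event{birth,death,switch}, N, a) per event
    events: Optional[list] = None

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {"t_min": self.times, "N": self.pop, "a_ug_per_ml": self.antibiotic}
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        self.to_dataframe().to_csv(path, index=False)

    def events_to_dataframe(self):
        """Per-event log of a stochastic run as a DataFrame."""
        import pandas as pd

        if self.events is None:
            raise ValueError("trajectory carries no event log")
        return pd.DataFrame(
            self.events, columns=["t_min", "event", "N", "a_ug_per_ml"]
        )


# ---------------------------------------------------------------------------
# The implicit antibiotic solution.
#
# Writing G(a) = a + K_M ln a, the degradation equation integrates to
# G(a(t)) = G(a0) - (E/V) * integral of N dt, for any N(t).  Inverting G is
# a Lambert-W evaluation: a = K_M * W(exp(G/K_M) / K_M).
# ---------------------------------------------------------------------------


def _g(a: float, K_M: float) -> float:
    """G(a) = a + K_M ln a (monotone increasing on a > 0)."""
    return a + K_M * math.log(a)


def _invert_g(c, K_M: float):
    """Solve a + K_M ln a = c for a > 0 (vectorised).

    Uses Lambert W where the argument exp(c/K_M)/K_M is representable; for
    very large exponents (tiny K_M or huge c) falls back to the contraction
    a <- c - K_M ln a, which converges at rate K_M/a << 1 in that regime.
    """
    c = np.asarray(c, dtype=float)
    x = c / K_M - math.log(K_M)  # log of the W argument
    a = np.empty_like(c)
    small = x < 700.0
    if np.any(small):
        w = lambertw(np.exp(x[small]))
        a[small] = K_M * w.real
    if np.any(~small):
        ci = c[~small]
        ai = np.array(ci, copy=True)  # a ~ c when K_M/a is tiny
        for _ in range(50):
            ai_new = ci - K_M * np.log(ai)
            if np.allclose(ai_new, ai, rtol=1e-14, atol=0.0):
                ai = ai_new
                break
            ai = ai_new
        a[~small] = ai
    return a if a.ndim else float(a)


def _validate(params: ModelParams, init: InitialCondition) -> None:
    if not isinstance(params, ModelParams):
        raise TypeError("params must be a ModelParams")
    if not isinstance(init, InitialCondition):
        raise TypeError("init must be an InitialCondition")


def antibiotic_crossing_time(
    params: ModelParams, n_cells: int, a0: float, volume: float
) -> float:
    """Time for the antibiotic to fall from a0 to a_th at constant cell count.

    Closed form: t = V * [a0 - a_th + K_M ln(a0/a_th)] / (E * n).  Returns
    +inf when no enzyme is present (n = 0 or E = 0).  Requires a0 >= a_th.
    """
    if a0 < params.a_th:
        raise ValueError(f"a0={a0} below threshold a_th={params.a_th}")
    if n_cells == 0 or params.enzyme_rate == 0.0:
        return math.inf
    dg = _g(a0, params.K_M) - _g(params.a_th, params.K_M)
    return volume * dg / (params.enzyme_rate * n_cells)


def advance_antibiotic(
    params: ModelParams, n_cells: int, a0: float, dt: float, volume: float
) -> float:
    """Antibiotic concentration after time dt of degradation at constant N.

    Solves a + K_M ln a = a0 + K_M ln a0 - E*n*dt/V exactly (Lambert W);
    the result lies in (0, a0].
    """
    if a0 < 0:
        raise ValueError(f"a0 must be >= 0, got {a0}")
    if dt < 0:
        raise ValueError(f"dt must be >= 0, got {dt}")
    if a0 == 0.0 or dt == 0.0 or n_cells == 0 or params.enzyme_rate == 0.0:
        return a0
    c = _g(a0, params.K_M) - params.enzyme_rate * n_cells * dt / volume
    return min(float(_invert_g(c, params.K_M)), a0)


def classify_outcome(params: ModelParams, init: InitialCondition) -> Outcome:
    """Analytic fate of a subpopulation.

    An empty sub-volume is KILLED.  Below the threshold concentration any
    occupied sub-volume SURVIVES (the antibiotic only decreases).  Above
    it, survival requires the initial count to reach the critical count
    N* = max(1, ceil(rho* v)): the total degradation capacity of the dying
    population, E*N/(gamma*V), must push the antibiotic below a_th before
    the population is effectively gone.
    """
    _validate(params, init)
    from .theory import critical_count  # local import: theory depends only on params

    if init.n_init == 0:
        return Outcome.KILLED
    if init.a_init <= params.a_th:
        return Outcome.SURVIVED
    n_star = critical_count(params, init.a_init, init.volume)
    return Outcome.SURVIVED if init.n_init >= n_star else Outcome.KILLED


def simulate_deterministic(
    params: ModelParams,
    init: InitialCondition,
    t_max: float,
    n_out: int = 200,
) -> Trajectory:
    """Exact deterministic trajectory of one subpopulation.

    Evaluates the closed-form piecewise solution on a grid of ``n_out``
    points spanning [0, t_max]; if the antibiotic crosses the threshold
    within the horizon the exact crossing time is located analytically and
    inserted into the grid (regime switching is an event, not a grid
    artefact).

    The outcome label follows the analytic classification: killing never
    reaches N = 0 in finite time, so KILLED is decided from the asymptotic
    antibiotic level rather than an arbitrary extinction cutoff, and the
    run is UNDETERMINED only if survival would occur after t_max.
    """
    _validate(params, init)
    if not (math.isfinite(t_max) and t_max > 0):
        raise ValueError(f"t_max must be positive and finite, got {t_max}")
    if n_out < 2:
        raise ValueError(f"n_out must be >= 2, got {n_out}")

    N0, a0, V = init.n_init, init.a_init, init.volume
    E, mu, gamma, K_M, a_th = (
        params.enzyme_rate,
        params.mu,
        params.gamma,
        params.K_M,
        params.a_th,
    )
    t = np.linspace(0.0, t_max, n_out)

    if N0 == 0:
        return Trajectory(t, np.zeros_like(t), np.full_like(t, a0), Outcome.KILLED)

    if a0 <= a_th:
        # growth from the start; degradation continues (no threshold in da/dt)
        with np.errstate(over="ignore"):
            pop = N0 * np.exp(mu * t)
        if a0 == 0.0 or E == 0.0:
            a = np.full_like(t, a0)
        else:
            c = _g(a0, K_M) - (E * N0 / (mu * V)) * np.expm1(mu * t)
            a = _invert_g(c, K_M)
        return Trajectory(t, pop, a, Outcome.SURVIVED, None)

    # kill regime: N decays, antibiotic falls; crossing iff N0 > rho* V,
    # i.e. the depletion fraction x = rho*V/N0 < 1.
    dg = _g(a0, K_M) - _g(a_th, K_M)
    if E > 0:
        x = gamma * V * dg / (E * N0)  # = rho* V / N0
        t_cross = -math.log1p(-x) / gamma if x < 1.0 else math.inf
    else:
        x, t_cross = math.inf, math.inf

    if t_cross <= t_max:
        outcome = Outcome.SURVIVED
        t = np.unique(np.concatenate([t, [t_cross]]))
    elif x > 1.0 or E == 0.0:
        outcome = Outcome.KILLED  # asymptotic level a_inf stays above a_th
    else:
        outcome = Outcome.UNDETERMINED

    kill = t <= t_cross
    pop = np.empty_like(t)
    a = np.empty_like(t)
    pop[kill] = N0 * np.exp(-gamma * t[kill])
    if E == 0.0:
        a[kill] = a0
    else:
        c = _g(a0, K_M) - (E * N0 / (gamma * V)) * (-np.expm1(-gamma * t[kill]))
        a[kill] = _invert_g(c, K_M)
    if np.any(~kill):
        n_c = N0 * math.exp(-gamma * t_cross)
        dt_g = t[~kill] - t_cross
        with np.errstate(over="ignore"):
            pop[~kill] = n_c * np.exp(mu * dt_g)
        c = _g(a_th, K_M) - (E * n_c / (mu * V)) * np.expm1(mu * dt_g)
        a[~kill] = _invert_g(c, K_M)

    return Trajectory(
        t, pop, np.minimum(a, a0), outcome,
        t_cross if t_cross <= t_max else None,
    )
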