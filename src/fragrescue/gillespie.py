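"""Hybrid stochastic engine: discrete birth-death events, continuous antibiotic.

Demographic noise matters when subpopulations are small: a handful of
cells may, by chance, outlast the antibiotic even when the deterministic
model says they die.  The engine is an event-driven (Gillespie-type)
simulation that is *exact* for this model:

* between events the cell count N is constant, so the single active
  propensity (death gamma*N above the threshold, birth mu*N below) is
  constant and the waiting time is exponential;
* at constant N the antibiotic has the implicit closed-form solution
  G(a) = a + K_M ln a decreasing linearly in time, so the concentration
  at the next event — and the exact moment a(t) reaches the threshold —
  are available without time stepping.

Each iteration therefore races the next demographic event against the
analytically located threshold crossing; whichever comes first happens.
No discretisation error is introduced at any point.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Callable, Union

import numpy as np

from .dynamics import Outcome, Trajectory, _g, _invert_g, classify_outcome
from .params import InitialCondition, ModelParams
from .theory import SurvivalEstimate

__all__ = [
    "SurvivalRule",
    "StochasticRunConfig",
    "gillespie_run",
    "estimate_survival_probability",
    "poisson_occupancy",
    "replicate_rng",
]


class SurvivalRule(enum.Enum):
    """When a stochastic run is declared survived.

    THRESHOLD_CROSSED: the instant the antibiotic falls below the
    threshold with at least one live cell — thereafter the process is a
    pure birth process and extinction is impossible, so this is exact.
    N_CAP: only once the population reaches a ceiling ``n_cap`` (useful
    for growth-limited extensions where late extinction is possible).
    """

    THRESHOLD_CROSSED = "THRESHOLD_CROSSED"
    N_CAP = "N_CAP"


@dataclass(frozen=True)
class StochasticRunConfig:
    seed: int = 0
    t_max: float = 1e5
    n_cap: int = 1000
    survival_rule: SurvivalRule = SurvivalRule.THRESHOLD_CROSSED

    def __post_init__(self) -> None:
        if not (self.t_max > 0):
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if self.n_cap < 1:
            raise ValueError(f"n_cap must be >= 1, got {self.n_cap}")
        if not isinstance(self.survival_rule, SurvivalRule):
            raise ValueError(f"invalid survival_rule {self.survival_rule!r}")


def replicate_rng(master_seed: int, replicate: int) -> np.random.Generator:
    """Independent, order-free substream for one replicate.

    Substream ``r`` is ``SeedSequence(master_seed, spawn_key=(r,))``: the
    same master seed always yields the same stream for replicate r,
    regardless of how many other replicates run or in what order.
    """
    return np.random.default_rng(np.random.SeedSequence(master_seed, spawn_key=(replicate,)))


def gillespie_run(
    params: ModelParams,
    init: InitialCondition,
    config: StochasticRunConfig,
    rng: np.random.Generator | None = None,
) -> Trajectory:
    """One exact stochastic realisation of a subpopulation.

    Returns an integer-population trajectory sampled at every event, with
    an event log ``(t, {birth,death,switch}, N, a)``.  KILLED iff N hits 0
    while the antibiotic is still above threshold; SURVIVED per the
    configured rule; UNDETERMINED if t_max arrives first (never silently
    relabelled).
    """
    if not isinstance(config, StochasticRunConfig):
        raise ValueError("config must be a StochasticRunConfig")
    if rng is None:
        rng = np.random.default_rng(config.seed)

    E, mu, gamma, K_M, a_th = (
        params.enzyme_rate,
        params.mu,
        params.gamma,
        params.K_M,
        params.a_th,
    )
    V = init.volume
    t, n, a = 0.0, int(init.n_init), float(init.a_init)
    times, pops, concs = [t], [n], [a]
    events: list = []
    t_cross: float | None = None

    def record(label: str) -> None:
        events.append((t, label, n, a))
        times.append(t)
        pops.append(n)
        concs.append(a)

    if n == 0:
        return Trajectory(
            np.asarray(times), np.asarray(pops, dtype=float), np.asarray(concs),
            Outcome.KILLED, None, events,
        )

    outcome = Outcome.UNDETERMINED
    g_th = _g(a_th, K_M)
    gval = _g(a, K_M) if a > 0 else -math.inf

    # --- kill regime: race each death event against the threshold crossing
    if a > a_th:
        while True:
            tau = rng.exponential(1.0 / (gamma * n))
            cross_dt = (gval - g_th) * V / (E * n) if E > 0 else math.inf
            if cross_dt < tau:
                t += cross_dt
                if t > config.t_max:
                    t = config.t_max
                    gval -= E * n * (config.t_max - times[-1]) / V
                    a = float(_invert_g(gval, K_M))
                    record("timeout")
                    break
                a, gval = a_th, g_th
                t_cross = t
                record("switch")
                break
            if t + tau > config.t_max:
                dt_left = config.t_max - t
                t = config.t_max
                if E > 0:
                    gval -= E * n * dt_left / V
                    a = float(_invert_g(gval, K_M))
                record("timeout")
                break
            t += tau
            if E > 0:
                gval -= E * n * tau / V
                a = float(_invert_g(gval, K_M))
            n -= 1
            record("death")
            if n == 0:
                outcome = Outcome.KILLED
                break
    else:
        t_cross = None  # started in the growth regime: no crossing event

    # --- growth regime: pure birth, antibiotic keeps degrading
    if n >= 1 and a <= a_th and outcome is not Outcome.KILLED:
        if config.survival_rule is SurvivalRule.THRESHOLD_CROSSED:
            outcome = Outcome.SURVIVED
        else:
            while n < config.n_cap:
                tau = rng.exponential(1.0 / (mu * n))
                if t + tau > config.t_max:
                    t = config.t_max
                    record("timeout")
                    break
                t += tau
                if E > 0 and a > 0:
                    gval -= E * n * tau / V
                    a = float(_invert_g(gval, K_M))
                n += 1
                record("birth")
            else:
                outcome = Outcome.SURVIVED

    return Trajectory(
        np.asarray(times),
        np.asarray(pops, dtype=float),
        np.asarray(concs),
        outcome,
        t_cross,
        events,
    )


def poisson_occupancy(lam: float) -> Callable[[np.random.Generator], int]:
    """Occupancy sampler: initial cell count ~ Poisson(lam)."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")

    def sample(rng: np.random.Generator) -> int:
        return int(rng.poisson(lam))

    return sample


def estimate_survival_probability(
    params: ModelParams,
    a_init: float,
    volume: float,
    init_sampler: Union[int, Callable[[np.random.Generator], int]],
    config: StochasticRunConfig,
    n_runs: int,
    engine: str = "stochastic",
    exclude_undetermined: bool = False,
) -> SurvivalEstimate:
    """Survival probability over replicate runs, with Wilson 95% CI.

    ``init_sampler`` is either a fixed initial count or a callable drawing
    one count per replicate (e.g. :func:`poisson_occupancy`).  Replicate r
    uses the substream :func:`replicate_rng` (config.seed, r), so the same
    master seed reproduces the same estimate whatever the execution order.
    UNDETERMINED replicates are reported in ``n_undetermined`` and count
    as non-survivals unless ``exclude_undetermined`` removes them from the
    denominator.
    """
    if n_runs < 1:
        raise ValueError(f"n_runs must be >= 1, got {n_runs}")
    if engine not in ("stochastic", "deterministic"):
        raise ValueError(f"engine must be 'stochastic' or 'deterministic', got {engine!r}")

    survived = undetermined = 0
    for r in range(n_runs):
        rng = replicate_rng(config.seed, r)
        n0 = init_sampler if isinstance(init_sampler, (int, np.integer)) else init_sampler(rng)
        init = InitialCondition(n_init=int(n0), a_init=a_init, volume=volume)
        if engine == "deterministic":
            outcome = classify_outcome(params, init)
        else:
            outcome = gillespie_run(params, init, config, rng).outcome
        if outcome is Outcome.SURVIVED:
            survived += 1
        elif outcome is Outcome.UNDETERMINED:
            undetermined += 1

    denom = n_runs - undetermined if exclude_undetermined else n_runs
    if denom == 0:
        raise RuntimeError("all replicates were undetermined")
    est = SurvivalEstimate.monte_carlo(survived, denom, n_undetermined=undetermined)
    return est
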