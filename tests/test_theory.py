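"""Phase-boundary and Poisson survival theory.

Poisson tails are checked against a brute-force pmf-summation oracle;
the boundary inverse is checked against a bisection oracle and the
round-trip identity.
"""

import math

import numpy as np
import pytest
from scipy.optimize import bisect

from fragrescue import (
    EstimateMethod,
    ModelParams,
    SurvivalEstimate,
    conditional_subpop_survival_prob,
    critical_count,
    critical_density,
    effective_mic,
    extreme_fragmentation_survival,
    occupancy_cv,
    phase_boundary_table,
    subpop_survival_prob,
    total_survival_prob,
)


def poisson_tail_bruteforce(lam: float, n_star: int) -> float:
    """Oracle: direct pmf summation of P(X >= n_star), X ~ Poisson(lam)."""
    total, term = 0.0, math.exp(-lam)
    for j in range(0, 4 * int(lam) + n_star + 60):
        if j >= n_star:
            total += term
        term *= lam / (j + 1)
    return total


class TestCriticalDensity:
    def test_reference_values_at_printed_precision(self, ref_params):
        # boundary densities for 15/35/55/75 ug/ml, as printed (2-3 s.f.)
        printed = {15.0: 4.1e7, 35.0: 7.4e7, 55.0: 1.04e8, 75.0: 1.3e8}
        halfdigit = {15.0: 0.05e7, 35.0: 0.05e7, 55.0: 0.005e8, 75.0: 0.05e8}
        for a, want in printed.items():
            assert abs(critical_density(ref_params, a) - want) <= halfdigit[a]

    def test_vanishes_at_threshold(self, ref_params):
        assert critical_density(ref_params, ref_params.a_th) == 0.0

    def test_below_threshold_rejected(self, ref_params):
        with pytest.raises(ValueError, match="boundary undefined"):
            critical_density(ref_params, 0.5)

    def test_strictly_increasing(self, ref_params):
        grid = np.linspace(ref_params.a_th, 100.0, 300)
        vals = [critical_density(ref_params, a) for a in grid]
        assert np.all(np.diff(vals) > 0)

    def test_shape_regimes_linear_vs_logarithmic(self):
        # a >> K_M: increment over a doubling ~ (gamma/E) * a (linear);
        # a << K_M: increment ~ (gamma/E) * K_M ln 2 (logarithmic)
        p = ModelParams(a_th=1e-6)
        gE = p.gamma / p.enzyme_rate
        a_hi = 1e3 * p.K_M
        d_hi = critical_density(p, 2 * a_hi) - critical_density(p, a_hi)
        assert d_hi == pytest.approx(gE * a_hi, rel=5e-3)
        a_lo = p.K_M / 1e3
        d_lo = critical_density(p, 2 * a_lo) - critical_density(p, a_lo)
        assert d_lo == pytest.approx(gE * p.K_M * math.log(2), rel=5e-3)


class TestEffectiveMic:
    def test_bulk_threshold_density_5e7(self, ref_params):
        # the highest survivable dose at 5e7 cells/ml is just under 20 ug/ml
        mic = effective_mic(ref_params, 5e7)
        assert mic == pytest.approx(19.9, abs=0.05)
        # independent bisection oracle on the boundary formula
        oracle = bisect(
            lambda a: critical_density(ref_params, a) - 5e7, 1.0 + 1e-9, 100.0, xtol=1e-10
        )
        assert mic == pytest.approx(oracle, rel=1e-8)

    def test_zero_density_gives_threshold(self, ref_params):
        assert effective_mic(ref_params, 0.0) == ref_params.a_th

    @pytest.mark.parametrize("rho", [1e6, 1e7, 1e8, 1e9])
    def test_round_trip_inverse(self, ref_params, rho):
        assert critical_density(ref_params, effective_mic(ref_params, rho)) == pytest.approx(
            rho, rel=1e-9
        )


class TestCriticalCount:
    @pytest.mark.parametrize(
        "a_init,v,expected",
        [(35.0, 1e-6, 75), (15.0, 1e-7, 5)],
    )
    def test_ceiling_values(self, ref_params, a_init, v, expected):
        assert critical_count(ref_params, a_init, v) == expected

    def test_single_cell_floor(self, ref_params):
        # sub-volume small enough that one cell exceeds rho*
        v = 0.5 / critical_density(ref_params, 15.0)
        assert critical_count(ref_params, 15.0, v) == 1


class TestPoissonTails:
    def test_against_bruteforce_oracle(self, ref_params):
        # lam = 5, N* = 5 in a 100 pl sub-volume at 15 ug/ml
        ps = subpop_survival_prob(ref_params, 15.0, 5e7, 1e-7)
        assert ps == pytest.approx(0.55951, abs=1e-5)
        assert ps == pytest.approx(poisson_tail_bruteforce(5.0, 5), rel=1e-12)

    def test_single_cell_threshold_is_occupancy_prob(self, ref_params):
        v = 0.5 / critical_density(ref_params, 15.0)
        rho = 5.0 / v
        assert subpop_survival_prob(ref_params, 15.0, rho, v) == pytest.approx(
            -math.expm1(-5.0), rel=1e-12
        )

    def test_zero_density_never_survives(self, ref_params):
        assert subpop_survival_prob(ref_params, 15.0, 0.0, 1e-7) == 0.0

    def test_large_occupancy_stable(self, ref_params):
        # lam = 1e4 must not overflow or underflow to garbage
        ps = subpop_survival_prob(ref_params, 15.0, 5e7, 2e-4)
        assert 0.0 <= ps <= 1.0
        assert ps == pytest.approx(1.0, abs=1e-6)  # lam far above N* here

    def test_conditional_tail(self, ref_params):
        cond = conditional_subpop_survival_prob(ref_params, 15.0, 5e7, 1e-7)
        assert cond == pytest.approx(0.56331, abs=1e-5)
        oracle = poisson_tail_bruteforce(5.0, 5) / -math.expm1(-5.0)
        assert cond == pytest.approx(oracle, rel=1e-12)

    def test_conditional_is_one_when_single_cell_suffices(self, ref_params):
        v = 0.5 / critical_density(ref_params, 15.0)
        assert conditional_subpop_survival_prob(ref_params, 15.0, 3.0 / v, v) == 1.0

    def test_conditional_rejects_empty_occupancy(self, ref_params):
        with pytest.raises(ValueError):
            conditional_subpop_survival_prob(ref_params, 15.0, 0.0, 1e-7)


class TestTotalSurvival:
    def test_two_subvolumes(self):
        assert total_survival_prob(0.5, 2) == pytest.approx(0.75)
        assert total_survival_prob(0.3, 1) == pytest.approx(0.3)

    def test_infection_scenario(self, ref_params):
        # 5000 cells at 5e7 cells/ml split into 100 sub-volumes, 35 ug/ml:
        # survival stays ~6%, i.e. the dose cannot reliably clear it
        ps = subpop_survival_prob(ref_params, 35.0, 5e7, 1e-6)
        assert ps == pytest.approx(poisson_tail_bruteforce(50.0, 75), rel=1e-9)
        assert ps == pytest.approx(5.8e-4, abs=0.05e-3)
        assert total_survival_prob(ps, 100) == pytest.approx(0.056, abs=0.002)

    def test_tiny_ps_large_m_precision(self):
        # log1p/expm1 path: 1 - (1-1e-12)^1e6 ~ 1e-6
        assert total_survival_prob(1e-12, 10**6) == pytest.approx(1e-6, rel=1e-6)

    def test_ps_non_decreasing_in_m_on_rescue_grid(self, ref_params):
        # the rescue-curve fragmentation grid (occupancy swept 200 -> 0.5);
        # on much denser grids the ceiling zig-zag can locally reverse Ps
        for a in (35.0, 55.0, 75.0):
            ms = np.unique([max(1, round(5000 / lam)) for lam in np.geomspace(200, 0.5, 12)])
            ps_vals = [
                total_survival_prob(
                    subpop_survival_prob(ref_params, a, 5e7, 1e-4 / m), int(m)
                )
                for m in ms
            ]
            assert np.all(np.diff(ps_vals) >= -1e-12)

    def test_log_ps_linear_in_subvolume_size(self, ref_params):
        # intermediate regime: log Ps correlates (negatively, tightly) with v
        ms = np.unique(np.round(np.geomspace(25, 10000, 200)).astype(int))
        v = 1e-4 / ms
        ps_vals = np.array(
            [
                total_survival_prob(
                    subpop_survival_prob(ref_params, 35.0, 5e7, vv), int(m)
                )
                for m, vv in zip(ms, v)
            ]
        )
        sel = (ps_vals > 0.01) & (ps_vals < 0.9)
        assert sel.sum() >= 10
        corr = np.corrcoef(np.log(ps_vals[sel]), v[sel])[0, 1]
        assert corr < -0.95


class TestExtremeFragmentation:
    def test_half_life_density(self):
        assert extreme_fragmentation_survival(math.log(2), 1.0) == pytest.approx(0.5)

    def test_zero_density(self):
        assert extreme_fragmentation_survival(0.0, 1e-4) == 0.0

    def test_large_population_always_survives(self):
        # 5000 cells in total: survival is 1 up to double precision
        assert extreme_fragmentation_survival(5e7, 1e-4) == pytest.approx(1.0, abs=1e-12)

    def test_matches_total_survival_when_single_cell_suffices(self, ref_params):
        # (1 - (1 - (1-e^-lam)))^m == e^{-rho V} independent of m
        rho, V = 7e6, 1e-7
        for m in (100, 1000, 10000):
            lam = rho * V / m
            ps = -math.expm1(-lam)
            assert total_survival_prob(ps, m) == pytest.approx(
                extreme_fragmentation_survival(rho, V), rel=1e-9
            )


class TestOccupancyCV:
    @pytest.mark.parametrize("lam,cv", [(25.0, 0.2), (4.0, 0.5)])
    def test_values(self, lam, cv):
        assert occupancy_cv(lam, 1.0) == pytest.approx(cv)

    def test_increases_with_fragmentation(self):
        rho, V = 5e7, 1e-4
        cvs = [occupancy_cv(rho, V / m) for m in (1, 10, 100, 1000)]
        assert np.all(np.diff(cvs) > 0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            occupancy_cv(0.0, 1e-7)


class TestSurvivalEstimate:
    def test_monte_carlo_wilson_interval(self):
        est = SurvivalEstimate.monte_carlo(55, 100)
        assert est.method is EstimateMethod.MONTE_CARLO
        assert est.ci_low < est.probability < est.ci_high
        # Wilson stays inside [0,1] even at the extremes
        lo = SurvivalEstimate.monte_carlo(0, 50)
        hi = SurvivalEstimate.monte_carlo(50, 50)
        assert lo.ci_low == 0.0 and hi.ci_high == 1.0

    def test_analytic_interval_degenerate(self):
        est = SurvivalEstimate.analytic(0.25)
        assert est.ci_low == est.probability == est.ci_high

    def test_inconsistent_interval_rejected(self):
        with pytest.raises(ValueError):
            SurvivalEstimate(0.9, 10, 0.0, 0.5, EstimateMethod.MONTE_CARLO)


def test_phase_boundary_table_schema(ref_params):
    df = phase_boundary_table(ref_params, [1.0, 15.0, 35.0])
    assert list(df.columns) == ["a_init_ug_per_ml", "rho_star_cells_per_ml"]
    assert df.rho_star_cells_per_ml.is_monotonic_increasing
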