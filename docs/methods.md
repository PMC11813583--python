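# Methods

## Model and assumptions

The defence model couples a threshold-switched birth–death population to
Michaelis–Menten toxin degradation. Its deliberate simplifications: killing
and growth are sharp exponentials switched at a single-cell threshold
concentration `a_th` (no Hill-type pharmacodynamics); antibiotic is lost
only to enzymatic degradation (no binding, decay or influx, so `a(t)` is
non-increasing and the system can switch regime at most once); enzyme
activity is proportional to the *live* cell count, with the per-cell enzyme
copy number and maximal turnover entering only through their product, which
is therefore a single parameter `enzyme_rate` (E). Sub-volumes are sealed:
no exchange of cells or antibiotic.

Default parameters (the reference preset) describe a β-lactamase-producing
strain in a microfluidic-droplet setting:

| parameter | default | units | meaning |
|---|---|---|---|
| mu | 0.01 | 1/min | growth rate below threshold |
| gamma | 0.045 | 1/min | death rate above threshold |
| enzyme_rate | 3.5e-8 | µg cell⁻¹ min⁻¹ | per-cell degradation capacity E |
| K_M | 6.7 | µg/ml | Michaelis constant |
| a_th | 1 | µg/ml | single-cell MIC |

Internal units are fixed (ml, min, µg, cells); pl and µm³ are converted at
the interface only (1 pl = 10⁻⁹ ml, 1 µm³ = 10⁻¹² ml).

## Closed-form solution strategy

Between demographic events (or in the deterministic model, within one
regime), N(t) is exponential, and writing G(a) = a + K_M ln a turns the
degradation law into dG/dt = −(E/V)·N(t). Every quantity follows
analytically:

* crossing time at constant N: `t = V·[a0 − a_th + K_M ln(a0/a_th)]/(E n)`;
* deterministic kill phase: `G(a(t)) = G(a0) − (E N0/(γV))(1 − e^{−γt})`,
  so the threshold is reached iff `N0 > ρ* V`, reproducing the phase
  boundary, and the crossing time is `−ln(1 − ρ*V/N0)/γ`;
* inverting G is one Lambert-W evaluation, `a = K_M·W(e^{G/K_M}/K_M)`; for
  exponents beyond double range (tiny K_M) a contraction iteration
  `a ← G_target − K_M ln a` is used instead (contraction rate K_M/a ≪ 1 in
  exactly that regime).

Deterministic killing never reaches N = 0 in finite time, so the KILLED
label is assigned analytically (the asymptotic antibiotic level stays above
threshold iff `N0 < ρ*V`) rather than by an arbitrary N < 1 cutoff. A run
is UNDETERMINED only when survival would occur beyond the requested
horizon. On the measure-zero tie `N0 = ρ*V` the analytic classifier counts
the population as surviving (the ceiling criterion `N ≥ ⌈ρ*v⌉` includes
equality) while the dynamic crossing time is infinite; classification and
simulation are guaranteed to agree only off this boundary.

The stochastic engine is exact for the same reason: with one active
reaction channel at constant propensity, the waiting time is exponential,
and the engine advances to whichever comes first — the sampled event or the
analytically located threshold crossing. Survival is declared the instant
the threshold is crossed with ≥1 cell (the process is then a pure birth
process and cannot go extinct); an N-cap rule is available for extensions
where that argument fails. Replicate r draws its generator from
`SeedSequence(master_seed, spawn_key=(r,))`, so estimates are reproducible
independently of execution order.

## Numerical choices

* G-inversion via `scipy.special.lambertw` (machine precision); the
  stochastic hot loop tracks G directly and only inverts when recording.
* Poisson tails via `scipy.stats.poisson.sf` (regularized incomplete
  gamma), stable to mean occupancies ≥ 10⁴; the brute-force pmf summation
  exists only as a test oracle.
* `Ps = 1 − (1−ps)^m` through `log1p`/`expm1` so ps ~ 10⁻¹² at m ~ 10⁶
  keeps precision.
* `N* = ⌈ρ* v⌉` is computed with a 10⁻⁹ relative slack before the ceiling
  so float noise cannot bump an exact integer product upward.
* The effective MIC inverts the strictly increasing, unbounded boundary by
  doubling the bracket until it straddles the target, then Brent's method.
* Monte-Carlo confidence intervals use the Wilson score (statsmodels):
  survival probabilities sit at 0/1 constantly, where Wald intervals
  degenerate.
* Metapopulation total-population series are summed on a common grid by
  linear interpolation of per-sub-volume trajectories (event times differ
  between sub-volumes).

## Synthetic-data / experiment design

There is no external data; the generator **is** the Poisson partition
sampler plus the two engines. The bundled presets fix the study
conditions: reference kinetics as above; partitioned scenarios use density
5×10⁷ cells/ml in 10⁻⁴ ml (5000 cells, the infection-scale scenario);
the rescue curve sweeps mean occupancy 200 → 0.5 on a 12-point log grid
(doses 15/35/55/75 µg/ml); the non-lethal curve uses doses 10–30 µg/ml on
m ∈ {1, 4, …, 1024}, chosen to stay below the single-cell-sufficient
regime where the conditional survival trivially returns to 1; the foraging
preset mirrors the defence kinetics with a 15 µg/ml substrate pool and a
1 µg/ml growth threshold on m ∈ {1, 10, 100, 1000}. Default replicate
count is 1000 (`--fast`: 100); the validation suite uses 200–500
replicates per point, sizes at which binomial envelopes are already
decisive for every qualitative claim.

Poisson occupancy emulates ideal random encapsulation (as in microfluidic
droplets). Real fragmented habitats may show over-dispersed or spatially
correlated occupancy, adsorption losses, heterogeneous sub-volume sizes,
and per-cell phenotypic variability — none of which are modelled, so
passing tests validate the mathematical claims under Poisson partitioning,
not those complications. Any occupancy law with density CV increasing
under fragmentation is expected to behave qualitatively alike; the
samplers accept a custom occupancy callable but no alternative law ships.

## The foraging model is a reconstruction

Only the qualitative behaviour of the enzymatic-foraging contrast is
pinned down externally (lag below a nutrient threshold, exponential growth
after, lag shortens with fragmentation). The implemented equations mirror
the defence model with the enzyme's sign reversed — substrate-limited
Michaelis–Menten release, sharp growth threshold, nutrient not consumed by
growth (hence exact mass balance n + s = s_init) — which reproduces every
qualitative statement; both zero-order (s_init ≫ K_M) and saturating
release are reachable through `s_init`/`K_M`. Yield-coupled consumption is
an extension point, not implemented.

## Design decisions on genuinely open points

* Survival ties: `N ≥ ⌈ρ*v⌉` (equality survives); documented above.
* The conditional (non-lethal) curve samples occupied sub-volumes directly
  (truncated Poisson by inverse CDF) rather than discarding empty draws.
* Whole-population Monte Carlo replicates the entire m-sub-volume system;
  the analytic `1 − (1−ps)^m` is reported alongside, never substituted —
  the independence assumption is validated, not assumed. For deterministic
  engines the per-sub-volume fate is exactly the threshold-count test, so
  the vectorised occupancy-matrix fast path is mathematically identical to
  looping the trajectory solver (and is cross-checked against it in the
  test suite).
* The boundary inverse at 5×10⁷ cells/ml gives ≈19.9 µg/ml as the bulk
  effective MIC, consistent with 20 µg/ml being the smallest lethal dose
  among {10, 15, 20, 30}.
* Plot rendering is out of scope; CSV/JSON outputs are the interface.

## Known limitations

* The exact-engine argument (survival once the threshold is crossed)
  relies on the absence of any death channel below threshold; models with
  residual killing need the N-cap rule and a horizon long enough to
  disambiguate, otherwise runs come back UNDETERMINED (they are counted
  and flagged, never silently relabelled).
* In the extreme-fragmentation limit the model predicts survival whenever
  any cell exists; physical sub-volumes of near-cell size strain the
  well-mixed and constant-parameter assumptions, so that limit should be
  read as a mathematical boundary, not a biological prediction.
* Deterministic trajectories report real-valued populations; discreteness
  matters only through N* and the stochastic engine.
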