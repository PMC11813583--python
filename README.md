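# fragrescue

Models of microbial **collective defence by enzymatic toxin degradation in
fragmented habitats** — for quantitative microbiologists and modellers
studying the inoculum effect, antibiotic treatment of compartmentalised
populations (droplets, pores, crypts, alveoli), and the ecology of shared
enzymatic benefits.

## The model

A population of `N` cells in a well-mixed volume `V` (the canonical example:
β-lactamase-producing bacteria exposed to a β-lactam antibiotic) grows at
rate μ while the antibiotic concentration `a(t)` is below a single-cell
threshold `a_th` and dies at rate γ above it; every live cell degrades the
antibiotic with Michaelis–Menten kinetics:

```
dN/dt = N [ μ θ(a_th − a) − γ θ(a − a_th) ]
da/dt = −(E N / V) · a / (a + K_M)
```

with `E` the per-cell degradation capacity and θ the Heaviside step. The
outcome is a race: survival requires degrading the antibiotic below `a_th`
before the population is gone, which happens exactly when the initial density
exceeds the critical density

```
ρ*(a_init) = (γ/E) [ a_init − a_th + K_M ln(a_init/a_th) ]
```

— the ecological phase boundary encoding the inoculum effect.

When the habitat is partitioned into `m` sealed sub-volumes `v = V/m`,
occupancies are Poisson(ρv), a sub-volume survives iff its count reaches
`N* = ⌈ρ* v⌉`, and the whole population survives iff any sub-volume does:
`Ps = 1 − (1 − ps)^m` with `ps` the upper Poisson tail at `N*`. Occupancy
fluctuations (and, for small populations, demographic birth–death noise —
simulated here by an exact event-driven hybrid scheme) let a fragmented
population survive doses that reliably kill the same population well-mixed:
habitat-fragmentation rescue. A contrasting enzymatic-*foraging* model
(enzymes release nutrient from a substrate; growth starts once nutrient
exceeds a threshold) shows the opposite character: fragmentation only
shortens the growth lag, never changes the outcome.

All deterministic trajectories and event times use exact closed forms
(the implicit solution `a + K_M ln a` + Lambert W); no ODE stepping.

## Worked example

The survivable dose for an unfragmented population at 5×10⁷ cells/ml:

```
$ fragrescue mic --rho 5e7
{"rho_cells_per_ml": 50000000.0, "effective_mic_ug_per_ml": 19.863400482406437}
```

so ~19.9 µg/ml is the bulk effective MIC: below it the population survives,
above it dies. The knife edge in a single 100 pl droplet at 15 µg/ml
(`ρ* v ≈ 4.13`, so 5 cells are needed):

```
$ fragrescue simulate --n-init 9 --a-init 15 --out t9.csv
outcome: SURVIVED
threshold crossing at 13.660 min
$ fragrescue simulate --n-init 3 --a-init 15 --out t3.csv
outcome: KILLED
```

Nine cells push the antibiotic below threshold after 13.7 min and regrow;
three cells lose the race. The fragmentation-rescue experiment (5000 cells
at 5×10⁷ cells/ml, doses 15–75 µg/ml, occupancy swept from 200 down to 0.5
cells per sub-volume):

```
$ fragrescue survival-curve --reps 1000 --seed 0 --out rescue.csv
```

writes per-(dose, m) Monte-Carlo survival probabilities with Wilson 95%
intervals next to the analytic `Ps`: ~0 at coarse fragmentation for
35–75 µg/ml, rising to 1 once single cells exceed the critical density.
Other subcommands: `phase-boundary`, `scan`, `nonlethal-curve`, `forage`,
`preset` (bundled scenarios; see `fragrescue preset list`).

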