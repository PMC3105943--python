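# Methods

## The models

### Full transcription model

Each of `n` identical cells carries a two-gene cascade.  Per cell the state
is (active gene-A promoters `Ac` of `a` copies, gene-A mRNA `Am`, protein
`Ap`, active gene-B promoters `Ba` of `b` copies, mRNA `Bm`, intracellular
protein `Bp_in`, converted activator `Cp`); one extracellular pool `Bp_out`
is shared by all cells.  The reactions, per cell:

| reaction | propensity/rate |
|---|---|
| activator binds promoter A / B | `α₁·Cp·(a−Ac)` / `α₁·Ap·(b−Ba)` |
| activator dissociates | `α₂·Ac` / `α₂·Ba` |
| transcription | `β·Ac` / `β·Ba` |
| mRNA decay | `δ_m·Am` / `δ_m·Bm` |
| translation | `γ·Am` / `γ·Bm` |
| protein decay | `δ_a·Ap`, `δ_b·Bp_in`, `δ_c·Cp` |
| export `Bp_in → Bp_out` | `κ·Bp_in` |
| uptake `Bp_out → Cp` | `ε·Bp_out` per cell (total `n·ε·Bp_out`) |

plus one global decay `δ_d·Bp_out` — 15·n + 1 channels.  Species are
absolute molecule counts in a unit volume, so deterministic concentrations
and stochastic counts are directly comparable.  All rates are s⁻¹; the
canonical set is `α₁ = 1.93e-4` (per activator molecule), `α₂ = 3.47e-2`,
`β = 1.16e-2`, `γ = 2.31e-2`, `δ_m = 1.16e-3`, `δ_a = δ_b = δ_c = δ_d =
3.47e-4` (protein half-life ≈ 33 min), `κ = 3.85e-4`, and a communication
rate `ε` of `2.31e-6` or `5.78e-7`.  Runs start with both genes off and a
pulse of 500 extracellular molecules as the transient inducer; it decays
with a ~33-minute half-life and does not influence the steady state.

Promoter binding is treated as **catalytic**: the bound activator molecule
is not consumed or held (and is not degraded while "bound"), matching the
gene-gate tradition of such models.  The deterministic fixed point is
provably identical either way — at steady state binding and unbinding
fluxes cancel — so the closed-form results are insensitive to this choice.
Because near-threshold stochastic behaviour could in principle differ, a
`sequester_activator` switch (default off) implements the alternative in
both engines; the mean-field consistency tests cover both.

### Minimal model

Three components (x, y, extracellular z), Michaelis–Menten synthesis
without cooperativity, explicit cell volume `V_c` and system volume `V_s`
(constraint `V_s > n·V_c`).  Identical cells reduce the system to three
ODEs with the export rate rescaled by `n·V_c/(V_s − n·V_c)`.  Defaults:
`k₁=k₂=k₃=0.02`, `δ₁=δ₂=δ₃=0.01`, `V_c=1`, `V_s=800`, so the gain is
`ξ = 8` and the threshold `n_c = V_s/(V_c(ξ+1)) = 800/9 ≈ 89`.  The figure
regime quotes no half-saturation constants; we default `K_x=K_y=K_z=1` (in
the model's concentration units), the only choice for which the threshold
reduces to a formula in ξ alone.  With non-unit constants, `n_c` is found
by bisection on the linearized loop gain instead.  The minimal model is
deterministic only.

## Closed-form steady state and thresholds

With `K = α₂/α₁`, `P_A = aβγ/(δ_m δ_a)`, `P_B = bβγ/(δ_m(κ+δ_b))` and the
communication gain `D_n = P_B·(nκ/(nε+δ_d))·(ε/δ_c)`, eliminating the
cascade variables yields one scalar fixed-point equation for the activator,
whose non-trivial root is

    Cp* = (D_n·P_A − K²)/(P_A + K)    (active when positive).

The active branch exists iff `D_n·P_A > K²`, which is algebraically
equivalent to `n > n_c = δ_d/(ε(abρ − 1))` with
`ρ = α₁²β²γ²κ/(α₂²δ_m²δ_a(κ+δ_b)δ_c)`; `abρ > 1` is necessary for any
finite threshold.  The `n → ∞` limit replaces `nκ/(nε+δ_d)` by `κ/ε`.
These forms were reconstructed from the model's reaction scheme and are
validated three ways: the closed form is a fixed point of the ODE right-hand
side to ~1e-16 relative residual; it matches damped fixed-point iteration of
the loop map and long-time integration to 1e-6 relative over randomized
feasible parameter sets; and it reproduces every published worked value
(ρ ≈ 7.2; n_c ≈ 97/22/45 and ≈ 50 at ε = 1.12e-6; Bp_out* ≈ 3200 at n = 50,
ε = 1.68e-6; the four copy-number ceilings 358000/308000/172000/143000).
One published near-threshold value (Bp_out* ≈ 23 at ε = 1.12e-6, n = 50) is
reproduced only as ≈ 25: within a percent of threshold the steady state is
extremely sensitive to the rounding of the printed rates, so this value is
noted but not relied on.

`n_c` is reported both as the real root and as `floor(n_c)+1` (the smallest
integer community strictly above threshold); sweeps treat `n` as continuous
because the formulas are, while simulation requires integer `n`.

## Numerics

* **ODE integration** — `scipy.solve_ivp` with LSODA, `rtol 1e-8`,
  `atol 1e-10`: promoter occupancies are O(1) while the pool reaches O(1e5),
  so loose tolerances would drown the small variables.  States are clamped
  at zero inside the RHS to absorb solver micro-undershoot.
* **Stochastic engine** — exact Gillespie direct method.  The production
  kernel (numba) aggregates the 15 per-cell channel types: the event type is
  drawn from 16 aggregate propensities maintained as exact integer sums,
  then the cell is drawn proportionally to its per-cell propensity by
  rejection sampling against a tracked per-species cap (with a linear-scan
  fallback after 64 rejections, and periodic cap refresh).  This two-stage
  sampling is statistically identical to the flat direct method — for the
  uptake channel all cells have equal propensity, so the cell is uniform —
  and makes 1e8-event runs (n = 500, 10000 min) take tens of seconds.  The
  naive flat-network SSA (`reference_ssa`) is kept as the independent
  oracle: the kernel is tested against it and against the exact Poisson
  stationary law of a birth–death network.
* **Seeding** — one base seed expands to per-run seeds via
  `numpy.random.SeedSequence` (masked below 2³¹); identical (params, seed)
  reproduce a run bit for bit.  Seeds are recorded in ensemble summaries and
  manifests.
* **Tau-leaping** — a fixed-step Poisson explorer with step-halving on
  negativity is provided for coarse sweeps only; nothing quantitative uses it.
* **Root finding** (minimal model) — the fixed point reduces to a scalar
  equation solved with Brent's method on a guaranteed bracket
  `(0⁺, k̃₃/δ₃)`; the origin is classified by the linearized gain.

## Ensemble statistics

"Active cell" means `Ap > 0` at the evaluation time, evaluated at
10000 min for steady-state statistics and 3000 min for transient
heterogeneity.  The per-run summary is the average `Ap` over the `n` cells
of that run at `t_end`; mean, SD and noise (= CV = SD/mean) are computed
across runs.  (Across-run statistics of per-run cell averages and pooled
cell-level statistics nearly coincide at 100 runs; the per-run convention
matches the deterministic comparison.)  Runs that stochastically
extinguish are included in the statistics — near threshold this is part of
the phenomenon, not an artifact.

## Problem sizes

Full-scale ensembles (100 runs × 10000 min × up to 500 cells) are long
jobs; the package's own test suite and presets therefore default to scaled
versions, chosen as follows and recorded in every manifest:

* Noise-table replication: 10 runs per (n, ε) row at the full 10000-min
  horizon, compared to the reference means within three standard errors.
* Threshold/ensemble behaviour: a "fixture" parameter set with every rate
  multiplied by 100.  Uniform scaling leaves ρ, `P_A`, `P_B`, all
  steady-state counts and the threshold structure exactly invariant (it is
  a pure change of time unit), while `ε` is then set so `n_c = 8` cells.
  Fixtures at n = 4 / 10 / 32 give guaranteed-quiescent, near-threshold
  (bistable) and reliably-active regimes that finish in seconds.
  Note the caveat: a 10-cell community just above an 8-cell threshold is
  *not* statistically identical to 140 cells above a 97-cell threshold —
  the near-threshold active level is ~28 Ap molecules per cell regardless
  of n_c, so a 10-cell active state holds ~280 molecules in total and is
  metastable (runs die back within a few multiples of the horizon), while
  140 cells hold ~4000 and persist.  Fixture tests therefore establish the
  qualitative regime structure, while the canonical-parameter tests
  (sub-threshold extinction at n = 50, endpoint bimodality at n = 140, the
  noise table at n = 200–500) cover the published operating points
  directly.

## What the generator does and does not emulate

Synthetic data here *is* the model: parameter sets plus seeds fully
determine every dataset.  The model itself omits, by design: cell division
and growth (n is constant), spatial arrangement and diffusion gradients
(the pool is well mixed — the decay-length check quantifies when that is
defensible: D = 91 μm²/s and an 18-min half-life give ≈ 376 μm, larger
than a ~100 μm tissue), receptor kinetics (uptake is one lumped first-order
step), and any negative-feedback patterning layer.  Passing tests therefore
say nothing about boundary formation or growing tissues; they validate the
threshold logic, steady-state levels and noise behaviour of the well-mixed
community.

## Known limitations

* The rejection-sampling caps make kernel runtime mildly state-dependent;
  pathological distributions (one cell holding nearly all molecules of a
  species) degrade toward the O(n) scan fallback but stay exact.
* `steady_state` classifies the regime by the sign of `Cp*`; it does not
  continue unstable branches or do bifurcation analysis beyond the
  threshold formula.
* Near-threshold quantities (both deterministic values within ~1% of n_c
  and stochastic activation probabilities) are intrinsically sensitive to
  parameter rounding; treat them qualitatively.
* The CLI loads whole trajectories into memory; multi-gigabyte temperature
  maps should use the library API with coarse snapshot grids.
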