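# Methods

## The model

`damagesim` simulates an asexual population of fixed size `N` in which each
cell carries two state variables: a heritable division rate `g` (offspring
per parent per generation, bounded by the environment's ceiling `g_max`)
and a dimensionless cellular damage load `D` (oxidised or misfolded
components). The model couples three processes:

**Damage accrues with growth and is removed by repair.** Within a cell,

    dD/dt = g·D_max − R(g)·D,

so a cell growing at rate `g` relaxes toward the equilibrium load
`D_eq(g) = g·D_max / R(g)`. Repair competes with growth for resources
through a linear trade-off,

    R(g) = R_max − s·(R_max − R_min)·g / g_span,   clamped to [R_min, R_max],

where `s` is the trade-off slope and `g_span` the growth rate at which
repair bottoms out. A cell devoting everything to repair achieves `R_max`;
a maximally dividing cell only `R_min`.

**Damage is heritable and relaxes over a generation.** A daughter starts
with its parent's load `D_p` (optionally a fraction of it) and reshapes it
through its own metabolism for a relaxation time `Δt`:

    D' = D_eq(g') + (D_p − D_eq(g'))·e^(−R(g')·Δt).

This is the exact solution of the damage equation over duration `Δt`.
`Δt = 0` makes damage purely parental; large `Δt` hands control entirely to
the daughter's own growth rate. `Δt` is the central experimental dial: it
sets how quickly the damage cost of fast growth is charged to the lineage
that incurs it.

**Damage kills offspring.** A daughter with load `D'` is nonviable with
Hill-function probability

    V(D') = D'^α / (K^α + D'^α),

half-maximal at the tolerance threshold `K` with steepness `α`. Each failed
reproduction attempt is a *selective death*; the cumulative count measures
the mortality load of adaptation.

**Generation loop.** Generations do not overlap. Parents are sampled with
replacement proportionally to `g`; each sampled parent's offspring mutates
its growth rate, inherits and relaxes damage, and survives with probability
`1 − V(D')`; sampling continues until `N` viable offspring exist. If
`1000·N` attempts cannot fill a generation the run aborts with an
extinction error — the regime where the mortality load would realistically
extinguish the population.

When damage is entirely offspring-determined (large `Δt`), the expected
viable-offspring production of a lineage is `w(g) = g·(1 − V(D_eq(g)))`;
its maximiser is the deterministic prediction for the evolved growth rate
(`predicted_equilibrium_growth`, the horizontal reference line of the
result figures).

## Environments, scenarios and the enrichment protocol

The ancestral environment permits `g ∈ [0, 1]`; enrichment raises the
ceiling to 2 instantaneously after the population has equilibrated
ancestrally (default burn-in: 1000 generations; the selective-death counter
is reset at the switch). Two commitments are made at ancestral
equilibration and persist after enrichment:

- **Damage tolerance** is anchored ancestrally: `K = D_eq(1)/2`, half the
  worst equilibrium load an ancestral cell can reach, and stays fixed in
  the new environment.
- **Repair physiology** is anchored ancestrally: the trade-off span stays
  `g_span = 1`, so cells growing beyond the ancestrally attainable range
  are already at minimal repair `R_min`. Raising the environmental ceiling
  changes what growth is *permitted*, not how the organism allocates
  resources. (Normalising the trade-off to the new ceiling instead would
  make every growth rate cheaper to repair at the moment of enrichment —
  an implicit physiological windfall that contradicts the reference
  scenario's premise that repair does not change between environments, and
  it abolishes the growth-rate reversal the model exists to study.)

Constant-environment scenarios (`constant_1.0`, `constant_2.0`) live in a
single environment from the start and anchor `K` and `g_span` to their own
ceiling.

The escape scenarios relax exactly one constraint on the enriched side:
`damage_tolerance` raises `K` to `D_eq(1)/1.1`; `cheap_repair` lowers the
trade-off slope from 1 to 0.25; `damage_reduction` lowers `D_max` from 5
to 2.

## Parameters and defaults

| parameter | default | meaning / why |
|---|---|---|
| `D_max` | 5 | damage accrual rate per unit growth (study design) |
| `R_max` | 5 | repair with full allocation (study design) |
| `R_min` | 0.1 | repair floor at maximal growth; see below |
| `repair_slope` | 1 (0.25 cheap repair) | linearity of the repair–growth trade-off |
| `K` | `D_eq(g_span)/2` | half-mortality damage threshold, anchored ancestrally |
| `alpha` | 4 (grid 2, 4, 10) | Hill steepness of damage–mortality |
| `delta_t` | 0.1 (grid 0.01–1.0) | offspring vs parental control of damage |
| `mutation_scale` | 0.05 | s.d. of the Gaussian growth mutation (study design) |
| `mutation_mode` | `jump` | 5% of offspring move ±0.05; `gaussian` mode: every offspring perturbed by N(0, 0.05²) |
| `inheritance_factor` | 1.0 | fraction of parental damage inherited |
| `N` | 1000 | population size (study design) |
| generations | 1000 | run length (study design) |
| replicates | 100 | per grid cell (study design; tests use 10–20) |

Two of these are not fixed by the study design and were chosen once, by
examining which settings reproduce the design's stated outcomes
simultaneously:

- `R_min` sets both the position of the viability "cliff" in growth-rate
  space (through `D_eq(g) → D_max·g/R_min` near the span) and, via the
  `K` anchoring, the absolute damage scale. The default 0.1 places the
  constant-environment equilibria at ~0.87–0.96 across the Hill-steepness
  grid (pooled ≈ 0.91/1.86 for ceilings 1.0/2.0) while keeping the
  enriched-environment cliff effective. Substantially smaller values let
  enriched populations outrun their damage for the whole run (no
  reversal); substantially larger ones pull the stable-environment
  equilibria well below ~0.91 and flatten the cheap-repair damage
  contrast. It is configurable everywhere (`model: {R_min: ...}` in the
  config file).
- The mutation kernel: the study design states only a "mutation rate" of
  0.05, which more plausibly names a per-offspring mutation *probability*
  than a Gaussian standard deviation, so the discrete kernel is the
  default. It also keeps standing variance low enough that the
  enrichment reversal at `Δt = 0.4` is robust, at the price of evolved
  means hugging ceilings more tightly (~1.97 rather than ~1.89 at
  `Δt = 0.01` after enrichment) than the Gaussian kernel, which in turn
  reproduces the 1.89 ceiling but weakens the `Δt = 0.4` reversal and the
  ceiling-2.0 pooled value. Both kernels ship; the choice is one config
  key (`model: {mutation_mode: gaussian}`).

## Numerical and design choices

- **Relaxation sign.** The offspring-damage update uses exponential decay
  toward `D_eq` (negative exponent). A positive exponent diverges and
  contradicts both limits (`Δt = 0` parental, `Δt → ∞` offspring).
- **Repair clamp.** `R(g)` is clamped to `[R_min, R_max]`, keeping `D_eq`
  finite and positive over the whole permitted growth range.
- **Viability timing.** Mortality is evaluated on the *offspring's* damage
  `D'`, after mutation and relaxation. This is the only ordering in which
  `Δt` modulates selection strength.
- **Mutation kernel.** Default (`jump`): each offspring mutates with
  probability 0.05, moving its growth rate by a fixed ±0.05 step (sign
  equiprobable), clamped to `[0, g_max]`. Alternative (`gaussian`): every
  offspring receives a zero-mean Gaussian step of s.d. 0.05. The
  trade-offs are described under "Parameters and defaults".
- **Batched sampling.** Reproduction attempts are drawn in vectorised
  batches sized by the running survival estimate and truncated at the
  attempt that fills the last slot, so the attempt stream is distributed
  exactly as one-at-a-time sampling with replacement.
- **Seeding.** Replicate seeds derive from the master seed via
  `SeedSequence(master, spawn_key=(cell_index, replicate))`: platform
  stable, order independent, and bit-reproducible.
- **Final state.** Reported summaries are the state at the final
  generation exactly (not a tail average); trajectories can be recorded
  every k generations for stability analysis.
- **Degenerate inputs.** An all-zero-growth population raises a distinct
  error (it cannot reproduce under the model's own logic) rather than
  falling back to uniform sampling.

## What the simulations show — and what they do not

With the defaults above the simulator reproduces the qualitative
programme: stable environments evolve growth just below their ceiling
(the shortfall is the baseline cost of repair; pooled ≈ 0.93 and ≈ 1.86
for ceilings 1.0 and 2.0); after enrichment, growth approaches the
doubled ceiling only when damage is mostly parental (`Δt ≤ 0.05`),
declines as offspring control rises, and at `Δt ≥ 0.4` ends below the
stable-environment value — the evolutionary reversal in which the raised
ceiling only supplies lethal fast-growing mutants. Cheap repair escapes
the reversal at every `Δt` and cuts the evolved damage load at `Δt = 0.1`
roughly threefold-to-fourfold relative to the reference; damage tolerance
and damage reduction raise growth more modestly and (for tolerance) raise
the damage load at every `Δt`.

Two caveats, both consequences of the relaxation dynamics under this
parameterisation, are documented rather than hidden:

- Absolute evolved damage loads are order 1–50: at equilibrium they
  cannot fall below `g·D_max/R_max ≈ g`, so damage loads well below 1 in
  a fast-growing population are unreachable under the convergent
  relaxation used here. Damage *contrasts* between scenarios are the
  meaningful output, not absolute loads.
- The selective-death load *peaks* at low-to-intermediate `Δt` after
  enrichment, where slowly relaxing damage eventually catches up with
  fast growers mid-run; the death load is not monotone in `Δt`.

The model emulates no particular organism: there is no plasticity, no
competition between evolved populations, no spatial structure, no sexual
reproduction, and fitness is growth and viability alone. Passing tests
show the implementation realises this model faithfully; they do not show
that real enriched microbial populations behave like it.

## Problem sizes used in the test suite

Quantitative checks run the full study design (N=1000, 1000 generations)
with 10–20 replicates per cell rather than 100; ordering and signature
checks run scaled-down populations (N=200, 300 generations, 10 replicates)
which preserve every qualitative ordering of the full design.
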