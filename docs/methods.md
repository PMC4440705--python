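# Methods

## Model

One cell is modeled as a small symmetric graph of subcellular compartments
plus a population of mitochondria.  The default geometry is a ring of 16
compartments in which each compartment is adjacent to its two nearest and
two next-nearest ring neighbors (degree 4).  Sixteen compartments follow
from the initialization protocol (two mitochondria per compartment, 32 in
total); the ring-with-next-nearest layout approximates the local
connectivity of a 2D patchwork partition of a disc while remaining simple
and deterministic.  Geometry enters the dynamics only through (a) fusion
feasibility — two mitochondria may fuse only when they occupy the same or
adjacent compartments — and (b) fission displacement — one daughter may be
placed uniformly in the original compartment or any neighbor.  Any
`CompartmentGraph` can be substituted; the simulator itself is
layout-agnostic.

A mitochondrion is an ordered chain of subcompartments, each holding
wild-type (W) and mutant (M) nucleoid counts.  Chains record fusion
history: fusing appends the donor's chain to the acceptor's (both sets of
internal fission sites survive, one new site forms at the junction), and
fission can cut only at a site.  Nucleoids follow the faithful-nucleoid
assumption: replication copies one nucleoid in place and identities never
mix within a nucleoid.

### Reaction channels

With s(R) = Rᵐ/(Kᵐ+Rᵐ) the OXPHOS-defect sigmoid (midpoint K, sharpness m;
s(K) = ½; s(1) ≈ 0.96 at the default K = 0.75, m = 11 — statements that
"s = 1" for fully mutant mitochondria are treated as the asymptotic bound):

* **Replication** (per nucleoid): (a_R0/N_ss)·(r_R,max·s(R̄)+1), multiplied
  by k_R for mutant nucleoids.  R̄ is by default the unweighted mean of the
  per-mitochondrion mutant fractions (the cell nucleoid fraction is
  available behind a flag).  The per-nucleoid basal rate a_R0/N_ss equals
  k_D at the nominal values, so a homoplasmic wild-type cell at the
  reference count N_ss = 320 replicates at a_R0 = 7.4/day, exactly
  balancing basal mitophagy.  Channels are aggregated per (mitochondrion,
  identity) — propensity = count × per-nucleoid rate — which is
  mathematically identical to one channel per nucleoid.
* **Mitophagy** (per mitochondrion): k_D·(r_D,max·s(Rᵢ)+1); removes the
  whole chain.  Removing the last mitochondrion flags the cell
  terminated-empty; its remaining samples are NaN and it is excluded from
  ensemble means.
* **Fusion** (per feasible pair): a_fus,0·r(Rᵢ)·r(Rⱼ) with
  r(R) = 1 − r_fus,max·s(R).  Donor/acceptor roles are a fair coin; the
  fused mitochondrion keeps the acceptor's compartment and identity.
* **Fission** (per mitochondrion with ≥ 2 nucleoids):
  V_F,max·Nⁿ/(K_Fⁿ+Nⁿ) of the total content N.  The propensity is clamped
  to zero below two nucleoids because each daughter must keep at least one
  (the raw Hill value there, ~1.2 × 10⁻⁴/day, is negligible).

### Fission mechanics

For a chain of length > 1 a fission site is drawn uniformly; the W-pools
and M-pools of the two subcompartments flanking the site are redistributed
by Binomial(pool, ½) draws — identity-blind, so the mutant count given a
side's total is hypergeometric — and the chain is cut.  The exchange is
rejection-resampled until both daughters (entire sub-chains) hold ≥ 1
nucleoid.  Chains may legitimately contain empty subcompartments, so a
drawn site can be *degenerate* (no exchange outcome can satisfy the ≥ 1
rule, e.g. an empty pool flanked by an empty sub-chain); degenerate sites
are redrawn, making the site uniform over viable sites.  At least one
viable site always exists for N ≥ 2.  Single-subcompartment mitochondria
split at a uniform cut k ∈ {1, …, N−1} with identities assigned by sampling
without replacement.  One daughter (fair coin) is placed uniformly over the
original compartment and its neighbors.

### Simulation algorithm

Exact SSA, direct method: exponential waiting times from the total
propensity, channel choice proportional to propensity, no approximation.
Per-mitochondrion propensity values are cached and refreshed only for
mitochondria touched by an event; compartment-level sums of the fusion
selectivity factors turn the O(pairs) fusion total into an O(compartments +
edges) expression.  The loop is compiled with numba (~1 µs/event), which is
what makes the ensemble experiments below desk-scale.  A pure-python
object-level implementation of the same event mechanics ships in the
package and is cross-validated against the kernel statistically in the test
suite.

Reproducibility: every source of randomness derives from one master seed
via numpy `SeedSequence([master, *counters])`; ensembles are embarrassingly
parallel with per-cell reproducibility, and identical seeds give
bit-identical trajectories.

### Numerical guards

* **Copy-number divergence.** When a mutant-dominated cell crosses the
  retrograde threshold, per-nucleoid birth (k_R·(a_R0/N_ss)·(r_R,max+1), up
  to ~0.46/day) can permanently exceed per-nucleoid death (~0.08/day): the
  copy number then grows exponentially without bound — the model has no
  copy-number homeostasis in this regime.  Cells reaching
  `max_nucleoids` (default 3200, ten-fold the reference count, the upper
  end of copy-number increases reported alongside clonal expansion) are
  flagged *saturated* and their statistics carried forward; such cells are
  effectively fixed for the mutant, so ensemble mutant-fraction means are
  barely affected.  Without this guard, several scenario and sensitivity
  settings are unsimulatable.
* Selection scans fall back to the last positive-weight candidate when
  floating-point cumulative sums undershoot; propensity caches are exact
  per-mitochondrion values recomputed on change, so no drift accumulates.

## Parameters (nominal)

| parameter | value | meaning |
|---|---|---|
| K (K_D = K_fus = K_R) | 0.75 | defect threshold midpoint (fraction) |
| m | 11.0 | threshold sharpness |
| k_D | 0.023 /day | basal mitophagy (30-day half-life) |
| r_D,max | 5 | mitophagy selectivity strength |
| a_R0 | 7.4 /day | basal cell-level replication (= k_D × 320) |
| r_R,max | 9 | retrograde amplification |
| k_R | 1 (2 with RA) | mutant replicative advantage |
| a_fus,0 | 0.123 /pair/day | basal pairwise fusion propensity |
| r_fus,max | 0.8 | fusion selectivity strength |
| V_F,max | 8.6 × 10⁴ /day | maximum fission propensity |
| K_F | 30 | fission half-saturation content |
| n | 6.0 | fission Hill exponent |
| ff_scale | 1 | common fusion+fission multiplier |

The three threshold midpoints are distinct fields perturbed equally in the
sensitivity analysis.  V_F,max is a constant multiple α = V_F,max/a_fus,0
of the fusion constant, so `ff_scale` changes fusion-fission frequency
without changing their ratio (or the steady-state nucleoid distribution).

## Protocols

**Premixing.**  Each cell starts as 32 mitochondria (two per compartment)
of 10 wild-type nucleoids and runs fusion-fission alone for 50 days, long
enough for the size distribution and spatial arrangement to reach steady
state for every mixing time up to τ = 30 days; for slower presets the
horizon extends proportionally (50·τ/30).  Fusion-fission conserves
nucleoids, so premixed cells hold exactly 320.

**Mixing time constant τ.**  From premixed cells, 160 of 320 nucleoids are
relabeled "mutant" — by whole mitochondria (block labeling), which
maximizes the initial between-mitochondria contrast that mixing erases; a
uniformly random labeling is available behind a flag — and fusion-fission
alone is run with selectivity disabled (labels must be dynamically inert).
τ is the first time the ensemble-mean COV of the per-mitochondrion label
fraction completes 63.2% of its change to the plateau, located by linear
interpolation on a 0.25-day grid.  The plateau is the mean over the
trailing 20% of the horizon, with a consistency check against the trailing
10% (disagreement beyond 5% of the total change raises an error asking for
a longer horizon).  The COV uses the population (n-denominator) standard
deviation; homoplasmic cells contribute a missing value, not zero.  Because
the pure fusion-fission generator rescales linearly in time, τ ∝ 1/ff_scale
exactly, and `scale_for_tau` inverts that anchor rather than searching.

**Clonal-expansion scenarios.**  Premix, relabel one uniformly chosen
nucleoid as the de novo mutant (preserving the 320 total), run the full
model for 300 days, and aggregate R_M^cell over the ensemble (mean, SD,
fraction cleared/fixed).  Presets cover mixing times 7.5/30/120 days, RA
(k_R = 2), non-selective fusion, high mitophagy selectivity
(r_D,max = 199), absolute fusion selectivity (r_fus,max = 1), and the
aged-cell setting with both selectivities halved.

**Mutant-rich episodes.**  Fusion-fission alone, non-selective fusion, one
mutant nucleoid.  An episode is the maximal interval a mitochondrion
lineage spends above the richness threshold (0.9 by default; with a single
mutant this means the mutant sits alone).  Episodes are tracked per
mitochondrion row: fission creating a rich daughter opens one, fusion of a
rich mitochondrion closes it; episodes still open at the horizon are
truncated there and counted as censored.  Occurrence normalizes episode
starts by mitochondrion-days (the time integral of the population size).

**Sensitivity analysis.**  Latin hypercube over the uncertainty ranges
k_R ∈ [1,2], τ ∈ [7.5,30] d, k_D ∈ [0.0069,0.023] /day, r_D,max ∈ [1,5],
r_fus,max ∈ [0,0.8], r_R,max ∈ [5,10], shared K ∈ [0.6,0.9]; one
clonal-expansion ensemble per point; outputs R̄_M^cell at days
50…250.  Indices are estimated by RS-HDMR: orthonormal shifted Legendre
expansions (degree 3 for single factors, 2×2 products for pairs — degrees
chosen to keep the joint least-squares fit overdetermined at a few hundred
samples; both are configurable), with S_i and S_ij read off as the
component-function variances over the total variance.  The estimator is
validated against closed forms (additive and product functions, the
Ishigami benchmark) and against an independent Jansen pick-freeze
estimator.  Effects are ranked by index magnitude at each analysis time and
averaged.  Cells per design point is a cost knob (default 100; the
package's own acceptance checks use smaller screens) — ranking, not index
values, is the robust output at desk scale.

## What the generator does and does not emulate

Premixed ensembles emulate the statistical steady state of fusion-fission:
unimodal nucleoid-content distribution, spatially mixed population.  They
do not emulate continuous-space positions, cytoskeletal transport,
membrane-potential dynamics, de novo mutagenesis (simulations start from
one pre-existing mutant), or inter-cell coupling.  Passing tests therefore
demonstrate internal consistency of the quality-control mechanism under
these idealizations, not agreement with any particular imaging or
sequencing dataset.

## Calibration tension and its resolution

The published parameterization is internally inconsistent, and this
implementation had to choose a side.  The printed rate constants
(a_fus,0 = 0.123 per feasible pair per day; the fission Hill parameters)
at the 320-nucleoid steady state force total fusion and fission rates near
100/day each under any connected 16-compartment layout.  Measured
consequences in this implementation: ~96 mitochondria per cell (not ~80),
τ ≈ 1.0 day at nominal rates (not the stated 7.5 days), episode occurrence
~2.1 × 10⁻³ /mito/day with ~0.27-day lifetimes (not 4.1 × 10⁻⁴ and 0.9
days).  Conversely, the stated anchors jointly imply a total event rate
near 30/day, which no reading of the printed constants produces; reducing
fusion contact raises τ and lifetimes but pushes the steady state *further*
from 80 mitochondria, so no geometry reconciles all anchors at once.  The
package implements the printed rate laws and values verbatim and reports
measured quantities.  The *relative* statements survive and are verified:
τ scales inversely with ff_scale; episode occurrence × lifetime is
invariant across fusion-fission frequency (the stated pairs satisfy this
too); clearance of a neutral mutant completes within 300 days; and the
selectivity-dependent reversal of whether faster fusion-fission helps or
hurts clearance is reproduced in the high-selectivity regimes.

## Known limitations

* In the fast-cycling regime that the printed constants produce, two
  published qualitative contrasts weaken: with nominal selectivity + RA the
  slow-mixing advantage (clears at τ = 30, accumulates at τ = 7.5) washes
  out, and at halved selectivities + RA the τ = 120 preset accumulates
  slowly rather than clearing.  Both orderings survive directionally in
  burden means but not as clear/accumulate dichotomies.
* The sensitivity ranking at desk scale places k_R first (robustly), but
  the mitophagy selectivity strength r_D,max lands below the k_R × k_D
  interaction and k_D rather than second — again a fast-cycling effect:
  with abundant short episodes, the absolute mitophagy rate matters more
  than its selectivity amplification.
* Saturated (copy-number-diverged) cells are frozen rather than simulated;
  their share is reported per ensemble (`n_saturated`).
* Episode bookkeeping attributes a fission that transfers richness between
  lineages as one closure plus one opening, which in multi-mutant settings
  differs from a "continuation" convention; with a single mutant the two
  coincide.
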