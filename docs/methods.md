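# Methods

## The carousel model

The package implements a mass-action model of the first step of GPCR
signaling in budding yeast: coupling between the pheromone receptor (Ste2),
the heterotrimeric G protein (Gpa1·Ste4/Ste18), and the receptor-associated
RGS (Sst2), whose GAP activity is folded into the hydrolysis rate constants.
The model composes the classical ternary-complex description of
ligand–receptor–G-protein binding with a three-state G-protein activation
cycle. Its 12 species are the eight receptor forms — free or ligand-bound
(`R`/`LR`), each uncoupled or coupled to the heterotrimer (`·G`), to GαGTP
(`·Gt`) or to GαGDP (`·Gd`) — plus free heterotrimer `G`, free GαGTP `Gt`,
free GαGDP `Gd`, and free Gβγ `Gbg`, the pathway output. Ligand is a clamped
external concentration (an infinite reservoir), and receptor and G-protein
totals are constant: the model describes the minutes-scale coupling
equilibrium, not receptor trafficking or synthesis.

The 19 reactions fall into five groups:

* 4 reversible ligand-binding reactions (one `kon_LR`/`koff_LR` pair for all
  receptor forms — ligand affinity is independent of coupling state);
* 6 reversible receptor–Gα coupling reactions (one `kon_RG`/`koff_RG` pair —
  coupling affinity independent of occupancy and nucleotide state);
* 3 irreversible GDP/GTP exchange reactions releasing Gβγ
  (`kE_G`, `kE_RG`, `kE_LRG`), which lump nucleotide exchange and trimer
  dissociation into a single step paced by GDP release;
* 3 irreversible hydrolysis reactions (`kH_Gt`, `kH_RGt`, `kH_LRGt`);
* 3 reversible GαGDP+Gβγ reassociation reactions
  (`kA_Gd`, with `koff_GdGbg = kA_Gd × Kd_GdGbg`).

The symmetry assumptions above are what reduce the network to 12 rate
parameters plus the two totals; they also pin the steady-state receptor
occupancy at the Langmuir fraction L/(Kd_LR+L) exactly, which the solver
tests exploit as a closed-form oracle. The three reassociation reactions are
treated as genuinely reversible: `Kd_GdGbg` is a model parameter and is
meaningless otherwise. The consequence — a small spontaneous Gd/Gbg pool
(about 3 nM at reference totals even with exchange disabled) — is asserted
in the tests. `kA_Gd` is a bimolecular rate constant (nM⁻¹s⁻¹);
`kH_LRGt` defaults to `kH_RGt` (the receptor-bound RGS accelerates
hydrolysis whether or not the receptor is occupied).

Units are nM and seconds throughout; molecule counts appear only at I/O
boundaries, converted through the cytosolic volume (36.4 fl by default, so
one molecule per cell ≈ 0.0456 nM).

Two structural variants extend the core network. The *extended* variant
makes RGS–receptor binding explicit: each receptor form gains an RGS-bound
twin (8 association reactions), and the GAP-accelerated hydrolysis rates
apply only to RGS-bound receptor-coupled GαGTP, with RGS-free receptors
hydrolyzing at the basal rate. With tight, abundant, fast-binding RGS this
variant collapses onto the simplified model (asserted to 1%). The default
RGS–receptor on-rate is 0.01 nM⁻¹s⁻¹ (10⁷ M⁻¹s⁻¹, a typical protein–protein
association rate); only the Kd (383 nM) and the totals are independently
constrained. The *two-pool* variant adds a receptor pool that couples G
protein normally but cannot bind ligand, modeling dominant-negative
non-binder alleles.

## Steady-state solver

Parameter-space scans span 8 decades per rate constant, producing stiffness
ratios up to ~10¹⁶; no single strategy is reliable there. The hybrid solver:

1. runs an undamped Newton iteration on the conservation-augmented system —
   all 12 species are unknowns, and one kinetic equation per conservation
   law is replaced by the law itself. The replaced (and thus only implicitly
   balanced) species is chosen per solve as the *largest* member of its law,
   so every small species keeps a directly enforced balance row. This
   choice, together with row/column equilibration and one step of iterative
   refinement, is what lets fixed points reach tight tolerances in double
   precision; eliminating small species instead leaves their implied
   balance carrying the rounding noise of the largest fluxes in the law.
   Line searches on a merit function stall on this problem (the scaled
   residual typically rises once before quadratic convergence), so steps
   are damped only to avoid grossly negative iterates.
2. on failure, falls back to implicit-Euler pseudo-transient continuation
   (adaptive step growth; as dt→∞ each step approaches a plain Newton
   step), followed by a Newton polish.

An explicit LSODA integration path (`method="integrate"`) is retained as an
independent oracle for tests; it integrates over geometrically growing
horizons (cap 10⁸ s) and stops at tolerance or at a trajectory plateau,
leaving final precision to the Newton polish.

Convergence is measured per species as |d[x]/dt| relative to
max(x, 10⁻¹² nM), with default tolerance 10⁻⁹ s⁻¹, after subtracting a
floating-point noise allowance of 64·eps times the species' absolute flux
turnover. The allowance matters: near a fixed point the summed mass-action
fluxes cancel to machine precision, and for stiff draws (turnover ~10⁶ nM/s
through nM-scale species) the raw residual can never reach 10⁻⁹; a 1%
perturbation of a fixed point still reports a residual many orders above
tolerance. Species are clipped at zero (not at an epsilon); non-converged
points are flagged, kept in scan denominators, and counted as non-robust.
Across 8-decade random draws about 0.3% of individual steady states fail to
converge under the default tolerance.

Dose-response curves solve one steady state per grid point, marching up the
ligand grid with the previous solution as the starting guess; the L=0 point
starts from the pre-equilibrated unliganded state (itself relaxed from all
receptor free / all G protein as trimer). Warm-started Newton solves in
3–6 iterations, ~0.5 ms per point.

## Dose-response summaries

The output is free Gβγ normalized to total G protein. The default ligand
grid is 0 plus 25 log-spaced points; the generic default spans 10⁻³–10⁵ nM,
while robustness classification centers the grid on each point's Kd_LR
(3 decades below to 4 above), because a fixed grid cannot contain a
saturating top for draws whose Kd itself spans 8 decades. *Amplitude* is
output at the top of the grid minus basal output. *EC50* is the primary,
fit-free definition: log-linear interpolation of the first upward crossing
of 0.5 by the baseline-subtracted, amplitude-normalized series; it is
undefined (NaN) when the amplitude is below the normal-amplitude floor.
*DoRA* (dose-response alignment) is the ratio EC50(output)/EC50(occupancy),
flagged when inside the configured band.

## Parameter sampling

The global scan draws the 12 kinetic parameters (including `kH_LRGt` as its
own axis) by Latin hypercube, log-uniform over 8 decades centered on each
reference value — exactly one point per equal-log-width stratum per
dimension (scipy's LatinHypercube, seeded). Kd parameters are sampled
directly and on-rates re-derived from (koff, Kd), so the binding symmetries
hold at every point. Receptor and G-protein totals are not sampled; receptor
abundance is varied deliberately by the robustness classifier. Draws carry a
JSON manifest (spec, seed, bounds, package version) from which they can be
regenerated bit-for-bit.

## Robustness classification and its thresholds

Each sampled point is classified from its dose-response curves at receptor
multipliers {0.1, 1, 10}:

* **normal amplitude** — reference-abundance amplitude ≥ 0.05 (normalized);
* **robust amplitude** — max/min amplitude ratio across multipliers ≤ 1.5;
* **robust EC50** — all EC50s defined and max/min ratio ≤ 3;
* **robust response** — both, the scan's main object;
* **DoRA** — EC50 ratio within [1/3, 3] at reference abundance.

Robust flags require a normal amplitude; solver failure at any multiplier
makes a point non-robust and flags it. All thresholds are configuration
keys, and the class fractions are strongly threshold-dependent: on a
2000-point calibration scan, tightening the amplitude criterion from a
1.5-fold to a 1.05-fold ratio moves the robust-amplitude fraction from
~14% to ~6%, and only much harsher protocols (e.g. ±100-fold multipliers
with a 0.005 absolute amplitude tolerance) push it below 2%. The defaults
above are deliberate, moderate choices — they keep the reference parameter
set classified as robust, consistent with its near-flat curves — and any
comparison of the resulting fractions with other analyses of this model
family should be read with that sensitivity in mind.

Restriction mining counts, for every ordered parameter pair, the exact
fraction of a subset satisfying log10(x) < log10(y) (optionally with a
margin in decades), reports pairs at or above the 0.95 threshold, and flags
fraction-1 pairs as *necessary*. Subsets below 50 points are refused. The
2D-histogram matrix uses one-decade log bins tiling each parameter's sampled
range, with 1D histograms on the diagonal; panels are tagged R<row><col> in
row-major order.

## What the synthetic sampler does and does not emulate

The Latin hypercube draws reproduce the statistical design of a global
parameter-space scan: stratified log-uniform marginals, independent axes,
fixed totals. They do not emulate correlations between biophysical rates in
real proteins (e.g. diffusion limits tying on-rates to off-rates via
affinity), nor measurement noise — every "observation" is a deterministic
steady state of the model itself. Passing scan tests therefore validates
the pipeline's classification logic and the model's parameter-space
geometry, not any property of experimental dose-response data.

## Numerical choices and degenerate inputs

Zero G protein, zero receptor, and dynamically silenced reactions
(rates ~10⁻³⁰ s⁻¹) are exercised in tests; conservation-law reduction
handles empty pools without special cases. EC50 of a non-monotone series
uses the first upward half-max crossing. Amplitude comparisons treat any
non-positive amplitude as non-robust. Ties in restriction mining
(log10(x) = log10(y)) count as unsatisfied.

## Known limitations

* The classification thresholds are configurable approximations of
  "insensitive"; no single set reproduces simultaneously every published
  summary statistic of this model family (see the fraction sensitivity
  above), so cross-study comparisons of the fractions are qualitative.
* With reference parameters the 10-fold receptor *reduction* costs up to
  0.078 normalized output at saturation (the 10-fold increase costs
  < 0.001): "robust" is approximate, not exact, at the reference point.
* The two-pool dominant-negative prediction yields ~64% of the all-binder
  maximum for a 50:50 mixture — above the idealized linear expectation of
  50%, because the reference transfer is mildly sensitized; the mixture
  output tracks the all-binder output at half occupancy instead.
* The full thermodynamically complete 38-parameter model is out of scope;
  exchange and hydrolysis are irreversible here by construction.
* No stochastic (SSA) or spatial simulation; the model is deterministic
  steady-state only.
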