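# Methods

## Tissue dynamics model

The ODE arm is a purely ecological model of a chronically stressed liver:
three well-mixed compartments (normal N, endocycling E, cancer C cells)
sharing one carrying capacity K. Its assumptions, in order of consequence:

- Normal and cancer cells grow logistically; cancer has the higher
  intrinsic rate (β = 0.45/day > α = 0.3/day), all cells share one
  background death rate δ = 0.1/day.
- Endocycling cells do not divide; they arise from normal cells at the
  stress-driven per-capita rate φ_N(t) (zero before the stress-onset time
  ψ = 50 days, then a rising logistic saturating at 0.02/day with midpoint
  125 days) and return to the normal pool by reductive mitosis — one
  polyploid cell becomes two normal cells — at rate φ_E(t) (a declining
  logistic from 0.05 to 0.01/day).
- Endocycling reshapes the microenvironment through its senescent,
  inflammatory, fibrotic secretory profile. This enters through two state
  couplings, both logistic in the endocycle frequency f = 100·E/(N+E+C)
  with midpoint 5% and slope 0.4/%: the per-division mutation rate μ(f)
  rises to a ceiling of 0.01, and the immune killing rate κ(f) of cancer
  cells falls from 0.16 to 0.01/day.
- Mutation is unidirectional (normal → cancer) and occurs at division:
  a fraction μ of the α·N·L division flux (L the logistic free-space
  factor) lands in C, the rest in N. The two fluxes sum to α·N·L
  identically, an invariant the tests enforce at 1e-10 relative tolerance.

**Per-capita ploidy reduction.** The ploidy-reduction terms in dN/dt and
dE/dt are per-capita (`2·φ_E·E` and `−φ_E·E`). A constant-flux variant
(terms `2·φ_E` and `−φ_E` without the factor E) is selectable with
`literal_phie: true`, but it is not the default because it manufactures
normal cells out of an empty tissue and destroys the extinction fixed
point; reductive mitosis is an event of individual endocycling cells.

**Endocycle frequency at extinction** is defined as 0 (avoids 0/0; makes
the empty tissue an exact fixed point).

**Therapy.** An endocycle-blocking therapy of efficacy b scales the
success probability η to η·(1−b): cells still *attempt* whole-genome
duplication (the φ_N·N outflow from N remains) but blocked attempts
produce no endocycling cell. `block_attempts=True` scales φ_N itself
instead, for sensitivity comparisons.

**Initial condition and horizon.** Simulations start at the pre-stress
quasi-equilibrium — the root of the system with φ_N forced to 0, found by
Newton iteration from the analytic logistic guess N ≈ K(1−δ/α(1−μ(0))).
Note that because μ(0) > 0, this equilibrium carries a small
mutation-sustained cancer pool, C* = α·μ(0)·N·L/(δ+κ(0)−β·L) ≈ 8.6 cells
at defaults; the tests pin this closed-form balance. The default horizon
is 400 days, long enough for homeostasis, stress-driven endocycle
expansion, and cancer invasion (C crossing 1% of K, the package's
operational invasion threshold) to all express in the baseline scenario.

**Numerics.** Adaptive RK45 (rtol = atol = 1e-8), checked against a
fixed-step classical RK4 at dt = 0.01 to 1e-4 relative agreement.
Populations that go negative within 1e-6 are clamped to zero and logged;
anything worse raises. Rate sigmoids use a numerically safe logistic, so
they saturate to their exact bounds in float64 rather than overflowing.

## Synthetic cohorts

The generator emulates segmented-cell feature tables from multiplexed
immunofluorescence of liver tissue microarrays. Defaults: 26 MASH samples
and 8 healthy controls, 300 cells per sample (~10⁴ cells), 30% of cells
out of cycle, endocycle-branch probability 0.10 in MASH vs 0.02 in
healthy tissue — the diseased-vs-healthy contrast the pipeline is meant
to detect. The 8-control count, per-sample size and the two branch
probabilities are generator conventions (no public cohort fixes them);
they are chosen so each healthy sample still contains a handful of
endocycling cells, which is the hard case for frequency estimation.

Cells live on a branched 1-D manifold: canonical G1→S→G2→M (wrapping to
G1), an endocycle branch sharing G1–G2 and diverging after G2, and a flat
non-proliferative branch. Marker mean log-intensities are plateaus per
phase with smoothstep transitions (half-width 0.015 in pseudotime),
encoded in a versioned JSON panel (`data/default_panel.json`) covering the
17 measured regulators. The panel encodes standard cell cycle biology
(Cyclin D1 peaking in G1, Cyclin E1/E2 in S, CDK1 in G2/M with Wee1
degraded at mitosis, CDK inhibitors p16/p21/p27 high out of cycle, pRB
low out of cycle) and the endocycle signature: RAIDD strongly up, Wee1
and CDK2 up, CDK1 down relative to canonical G2, with RAIDD declining
toward the branch exit as stress resolves. `PanelProfile.validate()`
enforces these orderings so a mis-edited panel fails loudly.

Measurement noise is log-normal (SD 0.2 on the log scale — multiplicative
noise is the norm for immunofluorescence), and each sample draws one
additive log-scale shift per marker (SD 0.1) as its batch effect.

What the generator does **not** emulate: spatial context and segmentation
errors, marker crosstalk between staining rounds, heavy-tailed outlier
cells, condition-dependent phase occupancy, or continuous variation in
disease severity. Passing tests therefore show the pipeline recovers a
*planted* manifold under realistic noise and batch structure — not that
it would resolve every real MASH liver.

## Preprocessing

Z-scoring is per sample and per marker, with the population (n)
denominator, so scores are bit-reproducible and sample batch offsets are
removed exactly — the cross-sample comparability the normalization exists
for. A `global_scaling` flag provides the single-statistics alternative.
Zero-variance markers map to 0 with a warning; single-cell samples are an
error naming the sample.

The proliferation gate fits a two-component Gaussian mixture to pRB
pooled across samples after normalization (log intensities when the table
is raw), removing cells with posterior > 0.5 for the lower-mean
component. Quantile initialization and a fixed seed make the fit
deterministic. If either weight falls below 0.02 the fit is declared
degenerate and the gate passes everything through; if the fitted mixture
has no density valley between its component means the input is flagged as
likely unimodal (the gate still applies, with a warning). Pooled-vs-
per-sample fitting and the 0.5 cutoff are package conventions, exposed as
parameters.

## Mapping

Clustering operates on the kNN graph (k = 30, Euclidean metric, union
symmetrization) built from the full z-scored feature space, not from the
2-D embedding — the embedding is for visualization and trajectory
geometry only. Leiden community detection (RB-configuration quality,
fixed seed) is run over a log-spaced resolution grid, taking the smallest
resolution that yields at least the target of five communities; the five
planted phases separate well before any of them fragments, so this scan
lands on exactly five clusters on default cohorts.

The 2-D layout is a diffusion-map embedding: adaptive-bandwidth Gaussian
kernel on each cell's k-neighborhood, symmetrized, row-normalized into a
diffusion operator, and projected on its two leading non-trivial
eigenvectors scaled by eigenvalue^t (t = 3). Diffusion coordinates
preserve continuous, branched trajectories, which is the property the
package contracts on (branch topology and phase adjacency), rather than
any particular embedding algorithm's output; UMAP is available as
`embedding_method="umap"`. Eigenvector sign is fixed by convention and
the start vector is seeded, so coordinates are reproducible.

Phase annotation is a codified rule table over cluster means of the
z-scored markers: the endocycle is the max-RAIDD cluster provided its
CDK1 is below the across-cluster median while Wee1 and CDK2 are above it;
among the rest, M = max CDK1, G1 = max Cyclin D1, S = max Cyclin E1/E2
composite, G2 = the remainder. Exact ties or failed signature checks
leave clusters unassigned with warnings; cluster counts other than five
are annotated best-effort rather than failing silently.

## Endocycle classifier

A 500-tree random forest (sqrt-features per split, unlimited depth, fixed
seed) on a stratified 70/30 split, reporting held-out AUC and accuracy
and impurity importances normalized to sum to one. Training labels
default to the annotated endocycle cluster, mirroring the
map-then-classify flow; note the circularity caveat — evaluating a
classifier on labels derived from the same feature space inflates its
metrics — which is why the tests also train against the generator's
planted labels (`true_phase`) for calibration. Per-sample endocycle
frequency is the percent of gated (proliferative) cells called endocycle;
condition comparison uses the Mann-Whitney rank-sum test by default
(robust for ~tens of samples of skewed percentages), with Welch's t-test
as an option.

## Problem sizes and determinism

Default verification runs use the default cohort (~10⁴ cells, 34
samples) for end-to-end checks and a ~1300-cell cohort for unit-level
pipeline tests; ODE checks use 10⁴ random states for the right-hand side
and five therapy efficacies for the sweep. Every stochastic component
(generator, mixture fit, Leiden, embedding start vector, forest, split)
takes an explicit seed, and fixed seeds reproduce outputs bit-for-bit.

## Known limitations

- The ODE model is deliberately qualitative: no spatial structure, no
  stochastic birth-death, no evolving traits; conclusions are about
  regime shapes (onset, invasion, monotone therapy response), not fitted
  trajectories.
- The annotation rule table assumes one endocycle-like cluster; tissues
  with several stress states would need an extended rule set.
- Diffusion coordinates compress the second axis by the eigenvalue
  ratio, so inter-phase distances are meaningful ordinally, not
  metrically.
- The per-sample z-score removes additive log-scale batch effects by
  construction; multiplicative (scale) batch effects are only attenuated.
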