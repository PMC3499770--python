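# Methods

## The model

The package analyses K condition tables X₁, …, X_K of gene × time-point
expression, all sharing one gene list and one time grid whose first point
is the common reference. The analysis is a multi-table extension of PCA:
instead of decomposing any single table, it decomposes a *compromise* —
an optimally weighted average of the per-table cross-product matrices —
and projects genes, time points and whole tables onto the shared
components.

Preprocessing per table: columns (time points) are centered and the whole
table is rescaled to unit total sum of squares, so that no condition
dominates the congruence structure merely by scale. A column z-scoring
variant (`table_norm: column_zscore`) additionally equalizes time points
within a table before the global rescaling; the default is table-level
scaling only, which keeps the congruence entries interpretable as
unnormalized RV numerators.

Cross-products are Sᵢ = XᵢXᵢᵀ over genes (or XᵢᵀXᵢ over time points in the
dual analysis, which is implemented literally as the same code path on
transposed tables). The congruence matrix C_ij = ⟨Sᵢ, Sⱼ⟩_F is entrywise
non-negative for such PSD matrices, so its leading eigenvector u₁ can
always be taken entrywise non-negative (Perron–Frobenius). Two weight
normalizations of u₁ are reported: sum-to-one weights (used to build the
compromise, making it a genuine weighted average) and unit-Euclidean-norm
weights (for K highly congruent tables these sit near 1/√K, e.g. ≈ 0.354
for K = 8, which is the natural scale on which such weights are usually
read). The two normalizations appear side by side in `table_weights.tsv`
because the literature uses both and they differ only by a positive
scalar.

The compromise S = Σ αᵢSᵢ is decomposed under the row-mass metric
M = diag(m) (uniform masses 1/n by default; 1/t in dual mode): the
generalized problem S = PΛPᵀ, PᵀMP = I is reduced to a standard symmetric
eigendecomposition of M½SM½ and back-transformed. Factor scores
F = SMPΔ⁻¹ equal PΔ algebraically; the identity is exploited as a
self-check in the test suite, while the production code uses the defining
product. Per-table scores Fᵢ = SᵢMPΔ⁻¹ average (with the compromise
weights) exactly to F. Loadings Q = XᵀMPΔ⁻¹ over the K·t stacked columns
satisfy QᵀAQ = I with A the diagonal of repeated table weights, which is
why the column contributions a_j q²_{j,b} sum to one per component; row
contributions mᵢf²ᵢ_b/λ_b sum to one because λ_b = Σᵢ mᵢf²ᵢ_b, and table
contributions are the per-table sums of their column contributions.

## Bootstrap significance

Stability of gene contributions is assessed by bootstrapping the *set of
tables*: each replicate draws K table indices with replacement, recomputes
the leading-eigenvector weights on the resampled congruence matrix, and
projects the resampled compromise onto the **fixed** full-data components
(F\* = Σ α\*ᵢ F_idx(i), a cheap weighted average of the precomputed
per-table scores). Refitting the decomposition per replicate would
misalign components across replicates through rotation and sign
indeterminacy; projection onto the fixed space is the standard resolution.
The bootstrap ratio mean/sd across replicates is read like a t statistic;
with the default `factor_scores` basis the flag is two-sided at the normal
quantile (|ratio| ≥ 2.576 at the 1% level), with the non-negative
`contributions` basis one-sided. When every resample is identical (e.g.
literally duplicated tables) the sd collapses; the ratio is then reported
as a signed infinity sentinel and the flag falls back to |mean| > 10⁻¹².

Two structural properties of this procedure matter for interpretation and
were measured explicitly on synthetic data during development:

* **Support limitation.** A temporal pattern carried strongly by only j of
  the K tables has a ratio ceiling of roughly √(K·j/(K−j)) — for K = 8 a
  factor needs about five strongly carrying tables before its genes can
  clear the 1% threshold reliably. Highly congruent table collections
  therefore yield many significant genes; heterogeneous ones few.
* **Static-structure channels.** Any structure that is identical in every
  table — notably a wide spread of static per-gene baselines, which
  survives column centering untouched — is perfectly resample-stable and
  is flagged as significant. That is mathematically correct behaviour
  (those genes do contribute reproducibly), but it means the method reads
  static expression-level differences as signal; analyses that care only
  about dynamics should remove gene means or interpret the affected
  component accordingly.

## Gene filtering

Genes enter the analysis only if, on the linear intensity scale, (a) some
condition shows a fold-change of at least 2 versus the reference time
point (in either direction) at two or more time points, and (b) some
condition's coefficient of variation over the time course reaches 1
(sample sd / mean; a per-condition criterion by default, with a pooled
variant via `cv_scope`). With one array per time point this is the
standard stand-in for a replicate-based test. A CV of 1 on the linear
scale is a demanding bar — it corresponds to a log2-sd of about 1.2, i.e.
sustained multi-fold swings — so the filter keeps strong responders and
high-variance genes only.

## Enrichment

Over-representation of gene sets among the selected genes uses the
hypergeometric upper tail P(X ≥ overlap) with the post-filter gene universe
as the population (configurable to a custom background), Benjamini–Hochberg
FDR across all tested sets, and a q ≤ 0.01 call threshold. Sets with fewer
than 3 members after intersection with the universe are skipped. Only
over-representation is tested; depletion is out of scope.

## Condition clustering

Pairwise condition similarity is the RV matrix; clustering is size-weighted
average linkage (UPGMA) on D = 1 − R_V, written out explicitly so that
ties merge deterministically at the lexicographically smallest pair of
cluster indices. Average linkage is reducible, so heights are monotone and
the dendrogram ultrametric; the Newick export places each leaf at half the
final merge height from the root.

## Synthetic data generator

The generator emulates the structure of a factorial light × temperature
time-course experiment: 8 conditions (darkness to high light crossed with
cold/control/heat, one being the control), 23 time points (dense 20-min
sampling to 360 min plus 5, 10, 640 and 1280 min — a grid that mixes
linear and near-logarithmic spacing), log2 intensities with a common
reference time point, and three disjoint gene modules each tracking one
latent temporal program:

| program | shape | condition scaling |
|---|---|---|
| diurnal | sin(2πτ/T), T = 1440 min | light level (3.0·√(μE/150)) |
| light | (1−e^{−τ/40})·e^{−τ/300} (fast rise, photoadaptation) | light contrast to control |
| temperature | 1−e^{−τ/720} (slow, sustained acclimation) | effective leaf-temperature contrast |

Default module sizes are 80/40/45 (the diurnal program involves the most
genes, as in real diurnal experiments). The *effective leaf temperature*
combines the air-temperature perturbation (±5.4 score units; cold is the
stronger stress) with a radiative term 0.3 × light contrast — irradiated
leaves run warmer than the air and darkened leaves cooler, so every light
shift also perturbs the temperature a leaf experiences. Gene values are
x(g,τ,c) = μ_g + β·L(g)·s(τ,c) + ε with β = 2, ε ~ N(0, (σ·d_g)²),
σ = 0.5 and a mild lognormal per-gene dispersion d_g (sd 0.3, capped at
3×). Baselines μ_g ~ N(8, 0.25) are deliberately tight: a wide static
baseline spread becomes a dominant stable between-table structure (see
above) and swamps the dynamics this benchmark is about. A quarter of the
background genes are *erratic* — wildly variable (sd 2.0 log2) in one
randomly assigned condition — modelling condition-specific dysregulation
and array artifacts, the realistic hazard of single-replicate designs;
they pass the any-condition CV filter but carry no reproducible
cross-table covariance, which is exactly the population the bootstrap step
must screen out, and they give the enrichment universe its unselected
majority. An optional *outlier* condition has its entire signal matrix
replaced by per-gene white noise of comparable magnitude, destroying its
within-module covariance blocks: the table-weighting step should and does
assign it the smallest weight and the lowest RV to the compromise.

The three temporal shapes are deliberately only weakly correlated on the
sampling grid (max |r| ≈ 0.4): on a front-loaded grid any two monotone
response curves correlate above 0.75 and no decomposition could attribute
them to separate components, which is a statement about experimental
design as much as about this generator.

What the generator does **not** emulate: probe-level microarray noise,
saturation, replicate structure, gene-gene regulatory correlations beyond
module co-expression, and missing values (the loaders reject them).
Passing the recovery tests therefore demonstrates that the machinery
identifies deviant covariance structure and reproducibly contributing
modules under the stated model — not that it would recover pathway
structure from any particular real data set.

## Numerical choices and degenerate inputs

* Symmetry/PSD tolerances: cross-products symmetrized as (S+Sᵀ)/2;
  eigenvalues clipped to 0 when above −10⁻⁶·λ₁, an error below that.
* Retained components: default 3, reduced automatically to the count of
  strictly positive eigenvalues; requesting a rank-deficient component is
  an error rather than a NaN.
* Sign convention: each retained eigenvector is flipped so its
  largest-|entry| coordinate is positive (ties broken by lowest index),
  making outputs reproducible across LAPACK builds.
* All-zero resampled congruence matrices (possible only for degenerate
  input) are redrawn with a logged warning.
* Output floats are written at 12 significant digits with deterministic
  row order, so identical inputs produce byte-identical files; every
  stochastic step takes a mandatory seed, recorded in the run manifest.

## Scale of the shipped study

The recovery study used throughout tests runs at n = 500 genes, t = 23
time points, K = 8 conditions, B = 200 bootstrap replicates over seeds
1–20 — sizes at which the full suite completes in seconds while leaving
the per-gene and per-table statistics well away from small-sample
degeneracy. The analytic identities are additionally exercised on ~50
random micro-instances (K ≤ 4, n ≤ 12, t ≤ 6) against the independent
SVD route.
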