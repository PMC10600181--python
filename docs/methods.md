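# Methods

This note records the statistical models the package implements, the
conventions chosen where the field leaves room, and what the synthetic
cohorts do and do not establish about real data.

## Data model

The central object is a subjects × features matrix `FeatureMatrix` with a
per-subject integer batch (scanner) label; companions are a binary
subjects × genes `MutationMatrix` and per-scanner `PhantomMeasurement`
vectors. All three round-trip through plain CSV (`subject_id` first,
batch column named `batch`), written at 17 significant digits and read
back with round-trip float parsing so write→read is exact.

## Correction methods

### Phantom ratio correction

Given phantom vectors from the reference scanner and the other scanner,
the per-feature ratio `r_g = phantom_ref_g / phantom_other_g` multiplies
every non-reference-batch subject's value of feature `g`; the reference
batch is untouched (default reference: batch 2). The operation is exactly
inverted by the reciprocal ratios. A phantom entry with magnitude below
`eps` (default 1e-12) is degenerate — a uniform cylinder genuinely yields
ill-defined values for some heterogeneity features — and raises an error
naming the feature; `skip_degenerate=True` downgrades this to
pass-through-with-warning. How near-zero phantom values were handled in
practice is not standardized anywhere; this guard is the package's own
convention.

### ComBat (parametric empirical Bayes, batch-only design)

Let `Y_ijg` be subject `j` of batch `i`, feature `g`, with batch sizes
`n_i`, `N = Σ n_i`, and `B` batches.

* Standardization (global mode): `α_g = Σ_i (n_i/N)·m_ig` with `m_ig` the
  batch means; `σ_g² = (1/N)·Σ_ij (Y_ijg − m_ig)²` (batch-size-weighted
  pooled residual variance); `Z_ijg = (Y_ijg − α_g)/σ_g`.
* Reference mode: `α_g` and `σ_g²` come from the reference batch alone.
* Per batch, `γ̂_ig = mean_j Z_ijg` and `δ̂²_ig = var_j Z_ijg` (ddof 1).
  Parametric priors by method of moments across features:
  `γ_ig ~ N(γ̄_i, τ_i²)`; `δ²_ig ~ InvGamma(λ_i, θ_i)` with
  `λ_i = (2s² + m²)/s²`, `θ_i = (m s² + m³)/s²` from the mean `m` and
  variance `s²` of the `δ̂²_ig`.
* EB fixed point, iterated until the maximum absolute parameter change
  drops below `tol` (default 1e-4, cap 100 iterations — typically < 10;
  hitting the cap warns rather than errors):
  `γ*_ig = (n_i τ_i² γ̂_ig + δ*² γ̄_i)/(n_i τ_i² + δ*²)`,
  `δ*²_ig = (θ_i + ½·Σ_j (Z_ijg − γ*_ig)²)/(n_i/2 + λ_i − 1)`.
* Back-transform `Y*_ijg = (σ_g/δ*_ig)(Z_ijg − γ*_ig) + α_g`. In
  reference mode the reference batch's parameters are pinned to (0, 1)
  and its rows are returned unchanged.

Only the parametric-prior variant with a batch-only design is
implemented (no biological covariates, no nonparametric priors, no
longitudinal variants). The implementation agrees with Bioconductor
`sva::ComBat` to ~1e-14 relative in both modes; the test suite repeats
that cross-check on a small matrix through `Rscript`.

A consequence worth knowing: on corrected data the empirical batch
variance ratio per feature differs from 1 *only* through EB shrinkage of
`δ²` (with no shrinkage the same-sample ratio is identically 1). At
~100 subjects per batch the shrinkage residual leaves roughly 10% of
features with batch variance ratios outside [0.8, 1.25]; this is a
property of parametric EB itself (sva behaves identically), not an
implementation artifact.

### Linear (limma-style) batch removal

Per feature, the least-squares fit of an intercept plus sum-to-zero
batch effects assigns batch `b` the effect `m_bg − mean_b(m_bg)`
(unweighted mean over batches), which is subtracted. For two batches
both corrected batch means equal the unweighted average of the observed
batch means exactly, and the operation is idempotent. Means are
equalized; batch *variance* differences are untouched — which is why a
strongly scale-inflated batch stays separable after this correction.

## Diagnostics

Distance-based diagnostics operate on z-scored features (mean 0, sample
SD 1; constant columns map to zeros with a warning) under Euclidean
distance. Radiomic features span many decades, so unscaled distances
would be dominated by the largest-magnitude feature; the choice of
scaling and metric is the package's own, as no standard exists.

* **Silhouette** with batch labels as clusters:
  `s_i = (b_i − a_i)/max(a_i, b_i)`, `a_i` the mean distance to the other
  same-batch subjects (self excluded), `b_i` the minimum over other
  batches of the mean distance to that batch. Conventions: 0/0 → 0;
  singleton-batch subjects score 0 with a warning. Both the mean of `s_i`
  and the mean of `|s_i|` are reported, since "closer to zero" is the
  well-mixed direction. Note that under self-exclusion two coincident
  identically-sampled batches do *not* give `s_i = 0` exactly (the
  same-batch mean excludes the subject, the other-batch mean includes its
  coincident twin); only fully degenerate coincident points do.
* **kBET rejection rate**: per repeat, draw one subject uniformly (with
  replacement across the `n_repeats = 1000` repeats), take its `k = 10`
  nearest neighbours excluding itself, and compute
  `χ² = Σ_b (O_b − k π_b)²/(k π_b)` against the global batch proportions
  `π_b`, with `B − 1` degrees of freedom and no continuity correction;
  reject at `p < α = 0.05`. The sampling unit (one subject per repeat)
  and the level are package conventions; the original kBET tool
  subsamples whole neighbourhood sets instead.
* **PCA** on the scaled matrix, with each component's sign fixed so its
  largest-magnitude loading is positive.
* **Before/after comparison**: Welch's two-sample t-test (two-sided),
  fed per-subject `s_i` for silhouette and per-repeat 0/1 rejection
  indicators for kBET. Degenerate zero-variance pairs return p = 1
  (equal means) or p = 0 (different means) with a warning. Welch rather
  than pooled-variance is a deliberate choice.

## Association scan

Genes with minor mutation frequency `min(f, 1−f) < 0.05` are removed.
For each (feature, gene) pair a univariable logistic regression of
mutation status on the *raw-scale* feature is fit by Newton/IRLS
(statsmodels; max 25 iterations, tolerance 1e-8), with Wald
`z = β̂₁/SE` from the inverse observed information and two-sided normal
p. Keeping features unstandardized means estimates are log-odds per
feature unit (magnitudes then span decades, mirroring how such tables
are reported); a `standardize` flag is available. (Quasi-)separation is
flagged via a scale-invariant guard — `|β̂₁|·SD(x) > 15` or a comparably
huge standardized SE — and flagged fits carry NaN p and are excluded
from adjustment with a warning rather than aborting the scan.

BH adjustment is applied within each feature across the retained genes
(family size = number of retained genes, 50 by default); the rank-1
arithmetic `p_adj = m·p` then matches the worked examples used in the
tests. Cross-method concordance is the squared Pearson correlation of
paired raw p-values over records converged in both tables (a
`-log10` option exists but is not the default, and whether a published
r² was computed on raw or transformed p-values is generally ambiguous —
the raw convention is declared here).

## Synthetic cohorts

`generate_cohort` emulates a two-scanner radiogenomic study:

* `n_subjects = 208` split ~50/50 over two batches; `n_features = 86`;
  `n_genes = 50` with per-gene mutation frequencies drawn uniformly from
  [0.08, 0.40] and resampled until every observed minor frequency is
  ≥ 0.05 (deliberately rare genes can be added via `n_rare_genes` to
  exercise the filter).
* Feature values `scale_g · (μ + shift_from_mutations + ε)` with
  `μ = 10`, `ε ~ N(0, 1)`, and `scale_g` log-uniform over 1e-3..1e3 —
  six decades of magnitude heterogeneity, the regime real PET texture
  features occupy.
* Causal couplings: each (feature, gene, slope) triple shifts mutation
  carriers' feature mean by `slope` within-batch SDs; the logistic refit
  in the scan estimates the reverse regression, and for shifts of this
  size the per-SD logistic slope approximately equals the shift.
  Defaults: (0, 0, +1.5), (7, 0, +1.0), (21, 3, −1.2).
* Batch effect on batch 1: `x → δ_g·x + γ_g·sd_g` with `sd_g` the
  empirical pre-shift SD — the location–scale class ComBat models. When
  `gamma`/`delta` are scalars they parameterize per-feature populations,
  `γ_g ~ N(γ, 0.5²)` and `δ_g ~ LogNormal(ln δ, 0.2²)`: scanners affect
  different texture features to different degrees, and a degenerate
  (constant-effect) configuration would make the EB priors fit pure
  sampling noise. Explicit vectors are used verbatim.
* Defaults describe a *location-dominated* effect: `γ = 2` SD, `δ = 1`
  (so scale factors spread ~±20% around 1 in both directions). This is
  the regime in which mean-only correction can work, matching the
  observed behaviour of limma-style correction on real multi-scanner
  data; a systematic ×1.5 scale inflation on all features would instead
  make batch separation variance-driven, which no additive correction
  can remove. The recovery benchmark uses `δ = 1.5` explicitly.
* Phantom vectors: base profile `10·scale_g` times each scanner's
  multiplicative factor (scanner 1 carries `δ_g`, scanner 2 is 1), plus
  optional relative Gaussian noise (default 0). Phantom correction in
  the simulation therefore removes exactly the multiplicative component
  and leaves the location shift — one plausible mechanism for the
  observed pattern that phantom correction underperforms statistical
  harmonization.
* All randomness flows from one seed through spawned child streams;
  identical configs give byte-identical cohorts.

What passing tests on these cohorts do **not** show: real scanner
effects need not be location–scale per feature (nonlinearities,
discretization and segmentation interactions are absent); features are
conditionally independent here, whereas real texture features are
strongly correlated; mutation calls are independent Bernoulli columns.
Conclusions about method *ranking* on real data therefore rest on the
paper trail of the field, not on these simulations alone.

## Numerical conventions and degenerate inputs

* Sample SD (ddof 1) everywhere user-facing; the ComBat pooled σ² uses
  1/N per its definition.
* Zero within-batch variance or a single batch is a hard error for
  ComBat; singleton batches are allowed for linear removal (a batch mean
  of one value is still defined) but not for ComBat.
* p-values must lie in (0, 1] for BH; empty families are errors.
* kBET requires `k < n_subjects` and every batch proportion > 0.
* Scans never abort on a single bad pair; failures are flagged per
  record.

## Problem sizes

Tests and the acceptance script run at the study scale (208 subjects,
86 features, 50 genes, 1000 kBET repeats, 4300 logistic fits per
method); the full suite completes in well under a minute and the
acceptance script in about half a minute on one CPU.
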