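# Methods

This note documents the models, conventions and numerical choices behind
`pathqc`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Problem setting

A biospecimen's usability for molecular profiling is summarized by two
quality metrics: the RNA Integrity Number (RIN, a continuous 1–10 score of
RNA degradation measured by capillary electrophoresis) and the autolysis
score (an ordinal 0 = none / 1 = slight / 2 = moderate / 3 = severe grade
of post-mortem self-digestion assigned by a pathologist). Both are costly:
RIN consumes tissue, autolysis scoring consumes expert time. `pathqc`
predicts both from the H&E slide image alone. Slides missing a label are
excluded from that label's task only; slides with fewer than two valid
patches after background filtering are excluded everywhere.

## Preprocessing

**Tissue mask.** The Sobel gradient magnitude of the luminance image
(0.299R + 0.587G + 0.114B, classic 3×3 kernels, reflecting boundaries) is
thresholded and cleaned up: 3×3 binary closing, hole filling, removal of
8-connected components under 64 px. Hole filling is needed because edge
detection outlines tissue regions — the interior of a homogeneous region
carries no gradient — so the raw thresholded mask is a set of rings.

The default threshold is the *lowest* cut of a three-class Otsu computed on
log(1 + gradient). Slide gradient histograms are typically tri-modal (flat
glass background, textured tissue interior, sharp tissue borders); a
two-class Otsu latches onto the border mode and keeps only edges, while
the lowest three-class cut separates background from tissue interior. An
explicit `gradient_threshold` overrides this heuristic, and
`postprocess=False` exposes the raw thresholded mask (used in tests against
a per-pixel reference implementation).

**Stain normalization (Macenko).** Optical density is
OD = −log10((I + 1)/256); the pseudo-count keeps OD finite at I = 0 and
maps white (255) to OD ≈ 0. Pixels with OD ≥ 0.15 in *at least one* channel
enter the estimation — an all-channel criterion would discard pure eosin,
which absorbs almost exclusively in green. The two stain vectors are the
1st/99th-percentile angular extremes of the high-OD pixels projected onto
their top-2 singular plane; columns are unit-normalized, clipped to the
non-negative orthant, and ordered hematoxylin-first (larger blue-channel
OD). Per-pixel concentrations are solved by least squares with negative
solutions clipped to zero (a fast surrogate for non-negative least squares
that differs only for pixels outside the stain cone), rescaled so each
stain's 99th-percentile concentration matches the target profile, and
re-rendered through the target basis. White pixels are a fixed point.

Degenerate single-stain images (rank-1 OD cloud) raise an error rather
than fabricating a second stain vector. The degeneracy cutoff is a
second-to-first singular value ratio of 0.02: 8-bit quantization alone
leaves a ratio near 0.01 on an exactly rank-1 image, so the cutoff sits
just above that noise floor. A default reference stain profile (the
widely used hematoxylin/eosin OD basis, with reference 99th-percentile
concentrations 1.9705 and 1.0308) ships as a constant so normalization is
reproducible without a reference image. Normalization is applied per
slide by default (one source profile per slide); per-patch application is
a caller choice.

**Tiling.** The patch grid is anchored at pixel (0,0), row-major, 0-based;
partial edge tiles are dropped. A patch is retained iff its tissue
fraction is ≥ 0.5 — the exclusion rule is "more than 50% background", so
the boundary is inclusive on the tissue side. Slides with fewer than two
retained patches fail the slide filter.

## Patch encoding and slide embedding

The encoder is an interface (name, dimension, deterministic
`encode(patch) -> R^d`). The shipped `SyntheticEncoder` computes
interpretable pixel statistics (channel means, SDs, minima, maxima) padded
to any requested d with fixed smooth transforms; heavyweight pretrained
vision transformers can be substituted without touching the pipeline.

A slide's P×d patch-feature matrix is aggregated element-wise into
[mean | std | min | max], length 4d. The standard deviation uses the
sample convention (divisor P − 1), well-defined because P ≥ 2 is enforced
upstream; the mean captures global morphology and the other three blocks
within-slide heterogeneity. Aggregation is permutation-invariant and
duplicating an existing patch never changes the min/max blocks.

## Quality models

Per tissue and target, the model is the lasso

    β* = argmin_β  1/(2N) ‖y − Xβ‖² + λ‖β‖₁   (pure L1, α = 1)

on z-scored features (zero-variance columns dropped) restricted to the top
5% of features by absolute Pearson correlation with the target (ties
toward the lower index). λ is selected on a 100-point log-spaced grid
descending from λ_max = max_j |x_jᵀ(y − ȳ)|/N (the smallest penalty at
which all coefficients vanish) to λ_max·10⁻⁴, by k-fold cross-validation
at minimum mean held-out MSE; among ties the larger λ (sparser model)
wins. Autolysis is modeled as a regression on the 0–3 ordinal scale and
converted to classes by rounding (clipped to [0,3]) when a classification
accuracy is reported; rounding is a declared convention, configurable by
post-processing the continuous predictions differently.

Z-scoring, feature screening and the λ search are all refit inside every
cross-validation fold, so no statistic of held-out slides influences any
fitting decision; the test suite asserts fold models are bit-identical
under perturbation of held-out rows. Whether to refit the z-scoring per
fold was a genuinely open choice; refitting is the leakage-safe option and
is the one implemented. The headline CV metric is the Pearson R of pooled
held-out predictions (one per slide), not the mean of per-fold Rs;
per-fold Rs feed the stability analysis. Evaluation is at the slide level
throughout — slides from the same donor are treated as independent
observations.

A constant training target (possible in small tissues with no label
spread) yields the degenerate intercept-only model (λ = ∞) rather than an
error.

**Train/test splitting.** The 70:30 split is stratified by tissue ×
RIN-quartile, with quartile cut points computed on the full labeled cohort
before splitting. Strata with fewer than two members are merged into the
nearest quartile within the same tissue. Test counts are apportioned by
largest remainder, so each stratum is within one slide of its target
fraction and the overall split matches round(N × 0.3) exactly.

## Pan-tissue framework

Stage 1 selects the top 500 features by one-way ANOVA F across tissue
classes (constant features rank last, ties toward the lower index) and
fits a multinomial logistic model with pure L1 penalty (saga solver,
internally standardized features). The penalty is chosen from a small
inverse-strength grid {0.01, 0.1, 1, 10} by stratified 5-fold CV at
minimum mean held-out deviance. Stage 2 routes a slide to the predicted
tissue's RIN and autolysis models when the classifier's maximum class
probability is at least 0.6; the boundary is read inclusively ("meeting"
the threshold covers the slide), which affects only measure-zero cases.
Uncovered slides receive no quality predictions unless an explicit
fallback flag routes them by argmax, in which case they are flagged.
Registry quality models are trained on all 4d embedding features (no 5%
screening is lost — screening still happens inside their own fit) with
fold assignment stratified on the binned target. Macro-AUC is the
unweighted mean of one-vs-rest AUCs; pairwise AUCs are one-vs-one on each
two-class subset with renormalized probabilities.

## Analyses

* **Variance explained.** For each covariate (tissue, Hardy scale, the
  complementary quality metric, age, sex) independently, the fraction is
  the R² of a univariate linear model of the target on that covariate
  (categoricals one-hot, rows with the covariate missing dropped
  pairwise). Fractions therefore need not sum to one. A joint
  (incremental-R², type-II-style) variant is available behind
  `method="joint"`; univariate is the default. An entirely missing
  covariate is absent from the report, not zero.
* **RIN–autolysis coupling.** Per-tissue Spearman ρ with average ranks for
  ties, two-sided p, and the conventional star labels (* p < 0.05,
  ** p < 0.01, *** p < 0.001, ns otherwise). No multiple-testing
  correction is applied; the table reports unadjusted p-values.
* **Feature sharing.** A feature's frequency is the number of tissues
  whose model gives it a nonzero coefficient; global top-20 per target,
  ties toward the lower index; the overlap set is the intersection of the
  targets' top lists. Heatmap ordering comes from complete-linkage
  Euclidean clustering applied independently to rows and columns.
* **Stability.** CV = σ/μ of per-fold correlations (sample SD); stable
  below 0.2, unstable above 0.5, intermediate between. A non-positive mean
  makes the ratio meaningless: CV is reported as NaN and the model labeled
  unstable, with a warning.
* **Preservation percentiles.** For each percentile q in {100, 90, …, 30},
  samples with observed value at or below the q-th percentile are retained
  and the Pearson correlation is recomputed — i.e. the *highest*-quality
  samples are removed first. q = 100 reproduces the full-sample R
  bit-for-bit; subsets under 5 samples or with constant observed values
  report missing.

## Synthetic data generator

The generator defines the study conditions for all tests and for the
acceptance script; it is deliberately simple enough that every expectation
can be computed analytically.

* **Embeddings.** Patch vectors are drawn from N(μ_t, I) where μ_t is a
  per-tissue signature with entries scaled by a separation factor
  (default 3.0, which makes tissues linearly separable — matching the
  near-perfect tissue discriminability of real slide morphology). Slides
  have 8–16 patches and are aggregated with the pipeline's own
  mean/std/min/max rule, so the planted structure passes through exactly
  the code path under test.
* **Quality labels.** The RIN latent is a fixed linear combination of 5
  designated signal coordinates of the slide's mean patch vector,
  standardized across the cohort; RIN = 6.5 + 1.5·latent + confounder +
  noise, clipped to [1,10] and rounded to two decimals — centering most
  slides in the 6–8 band typical of post-mortem cohorts. The default
  residual noise SD is half the signal SD, which caps the attainable
  prediction R near 1/√1.25 ≈ 0.894. Autolysis discretizes a negatively
  loaded copy of the same latent plus independent noise through fixed
  quantile thresholds (0.5 / 0.8 / 0.95), skewing mass toward classes 0–1
  and guaranteeing the negative RIN–autolysis coupling seen in real
  tissue. An optional Hardy-scale proxy adds a death-circumstance
  confounder (default off). Note the latent is cohort-wide: with strongly
  separated signatures much of its variance is between tissues, so
  within-single-tissue fits see an attenuated signal — pooled or
  pan-tissue evaluation is the intended use of the default spec.
* **Tiles.** White background plus elliptical blobs rendered through the
  two-stain Beer–Lambert model (known H/E vectors, smooth positive
  concentration fields). Blobs are added until the rendered tissue
  fraction reaches the request, and the exact mask is emitted alongside.
  The tiles exercise masking, stain estimation and tiling; they do not
  model real histologic texture, focus artifacts, pen marks or autolysis
  morphology.

Everything is driven by NumPy's PCG64 generator from a single seed; fixed
seeds give bit-identical datasets. Because the generator plants a *linear*
link into Gaussian features, passing tests demonstrate correctness of the
pipeline's statistics and plumbing — not that real degradation morphology
is linearly decodable; that question can only be answered on real cohorts.

## Problem sizes and defaults

The reference simulation is 5 tissues × 100 slides with d = 64 patch
features (256 embedding features); the pan-tissue evaluation in the
acceptance script uses a 70:30 split of that cohort, with the classifier's
ANOVA-F selection capped at the 256 available features. These sizes were
chosen so the full acceptance run completes in well under a minute while
keeping every stratum large enough for stratified 5-fold fitting. Pipeline
defaults (512×512 patches, 50% background cap, ≥2 patches per slide,
5 folds, 70:30 split, top-5% screening, 500 classifier features, 0.6
confidence threshold) are the published operating point of the method and
are all overridable through `RunConfig` or CLI flags.

## Known limitations

* The shipped encoder is an image-statistics stand-in; predictive power on
  real slides depends on plugging in a pathology foundation-model encoder.
* Macenko normalization assumes two stains; slides with additional
  chromogens or heavy artifacts violate the model.
* Autolysis is treated as a regression target; the rounding-based class
  accuracy ignores the ordinal scale's unequal spacing.
* The lasso is linear in the embedding; interactions between morphology
  statistics are not modeled.
* Pan-tissue routing requires every classifier class to have a registry
  entry; unseen tissue types are an error, not a graceful fallback.
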