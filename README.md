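# pathqc

Predict biospecimen quality — the RNA Integrity Number (RIN, 1–10) and the
histological autolysis score (0–3) — directly from H&E-stained histology
slide images.

Measuring RIN consumes tissue (capillary electrophoresis of extracted RNA),
and autolysis scoring requires expert pathologist review. Both gate whether
a banked specimen is usable for molecular profiling. `pathqc` estimates both
non-destructively from routine slide scans, for biobanks and retrospective
cohorts where destructive or manual quality control does not scale.

## Method

The pipeline has four stages:

1. **Preprocessing.** Background is removed with Sobel edge detection
   (gradient of luminance, automatic threshold, morphological cleanup), the
   image is color-normalized with Macenko's method (stain vectors from the
   SVD of high-optical-density pixels, percentile-extreme angles), and the
   slide is tiled into non-overlapping 512×512 patches. Patches with more
   than 50% background are dropped; slides with fewer than two valid
   patches are excluded.
2. **Patch encoding.** A pluggable encoder maps each patch to a
   d-dimensional feature vector z_sp. A deterministic image-statistics
   encoder ships with the package; any pretrained vision encoder satisfying
   the same contract can be plugged in.
3. **Slide embedding.** A slide with P patches is summarized by the
   element-wise statistics of its patch-feature matrix:

       x_s = [mean_p(z_sp) | std_p(z_sp) | min_p(z_sp) | max_p(z_sp)]

   a 4d-length vector (4096 for d = 1024).
4. **Quality models.** Per tissue and per target, a lasso regression

       β* = argmin_β  1/(2N) ‖y − Xβ‖² + λ‖β‖₁

   with features z-scored, the top 5% most target-correlated features
   pre-selected, and λ chosen by 5-fold cross-validation at minimum mean
   held-out MSE over a 100-point log-spaced grid. All fitting steps are
   refit inside each fold; performance is the Pearson R of pooled held-out
   predictions.

A **pan-tissue** front end removes the need to pick a tissue model by hand:
a multinomial L1 logistic classifier (on the top-500 ANOVA-F features)
predicts the tissue type, and slides whose classification confidence is at
least 0.6 are routed to that tissue's RIN and autolysis models.

The `analysis` module adds the surrounding diagnostics: variance explained
by technical confounders, per-tissue Spearman coupling of RIN and
autolysis, cross-tissue feature-sharing with hierarchical clustering, fold
stability via the coefficient of variation (stable < 0.2, unstable > 0.5),
and the preservation-percentile robustness curve.

## Worked example

Everything below runs on synthetic data from the built-in generator
(`pathqc.synthetic`), which emulates the statistical structure the pipeline
assumes: tissue-specific Gaussian patch signatures plus a planted linear
link from a small feature subset to RIN and an anti-correlated autolysis
score.

```python
import numpy as np
from pathqc.synthetic import SyntheticSpec, generate_embedding_dataset
from pathqc.tissue_models import cross_validate_tissue, stratified_split
from pathqc.pan_tissue import train_pan_tissue, route_and_predict, evaluate_pan

spec = SyntheticSpec(seed=1)          # 5 tissues x 100 slides, d = 64
ds = generate_embedding_dataset(spec)

_, r, rmse = cross_validate_tissue(ds.records, ds.X, "rin", seed=1)
print(f"pooled 5-fold CV: RIN R = {r:.3f}, RMSE = {rmse:.3f}")

train_ids, test_ids = stratified_split(ds.records, test_fraction=0.3, seed=1)
pos = {rec.slide_id: i for i, rec in enumerate(ds.records)}
tr, te = [pos[s] for s in train_ids], [pos[s] for s in test_ids]
model = train_pan_tissue([ds.records[i] for i in tr], ds.X[tr], k=256, seed=1)
routed = [route_and_predict(ds.X[i], model, slide_id=ds.records[i].slide_id)
          for i in te]
report = evaluate_pan(routed, [ds.records[i] for i in te])
print(f"pan-tissue test: accuracy = {report.accuracy:.3f}, "
      f"coverage = {report.coverage:.3f}, RIN R = {report.rin_r:.3f}, "
      f"autolysis accuracy = {report.autolysis_accuracy:.3f}")
```

Output:

```
pooled 5-fold CV: RIN R = 0.890, RMSE = 0.774
pan-tissue test: accuracy = 1.000, coverage = 1.000, RIN R = 0.867, autolysis accuracy = 0.713
```

The pooled CV correlation of 0.89 shows the lasso recovering the planted
RIN signal through the embedding (noise in the generator caps the
attainable R near 0.9); classification accuracy and coverage of 1.0 reflect
the widely separated synthetic tissue signatures, and the routed RIN R on
the held-out 30% is close to the in-cohort CV value, i.e. the two-stage
routing loses little accuracy.

The same workflow is available from the shell:

```bash
pathqc simulate embeddings --seed 1 --out sim/
pathqc train --embeddings sim/embeddings.tsv --manifest sim/manifest.tsv \
             --target rin --seed 1 --out models/
pathqc pan-train --embeddings sim/embeddings.tsv --manifest sim/manifest.tsv \
                 --seed 1 --out pan/
pathqc analyze --manifest sim/manifest.tsv --models models/ --out report/
```

`pathqc preprocess` and `pathqc embed` cover the image stages for PNG/TIFF
slide images.

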