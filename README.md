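# pleuratex

Second-order grey-scale texture analysis of the pleural line in lung
ultrasound.

In acute hypoxemic respiratory failure, distinguishing the permeability
edema of ARDS from cardiogenic pulmonary edema (CPE) on lung ultrasound is
hard: both produce B-lines, and the pleural line looks speckled in either
case. The texture of the pleural line differs, though — ARDS derangement of
the sub-pleural structure produces an inhomogeneous pleural line, CPE
relatively spares it — and second-order statistics can quantify that
difference. `pleuratex` implements this quantification for clinicians and
image-analysis researchers working with B-mode ultrasound: it turns an
8-bit frame plus an operator-drawn region of interest (ROI) into twelve
texture features, and turns per-subject feature tables into diagnostic
accuracy statistics.

## Method

For a frame quantized to `Ng = 16` uniform grey levels, the grey-level
co-occurrence matrix (GLCM) `P(i, j; d, θ)` is the probability of finding
level `i` at displacement distance `d ∈ {1, 2, 3, 4}` and direction
`θ ∈ {0°, 45°, 90°, 135°}` from level `j`, counting only pixel pairs that
lie entirely inside the ROI mask and accumulating symmetrically (so
`P = Pᵀ` exactly). From each matrix, with marginal mean/SD `μ, σ` and the
level-sum distribution `p_{x+y}`:

| feature | definition |
|---|---|
| contrast | `Σ (i−j)² p(i,j)` |
| cluster shade | `Σ (i+j−2μ)³ p(i,j)` |
| cluster prominence | `Σ (i+j−2μ)⁴ p(i,j)` |
| entropy | `−Σ p log₂ p` |
| variance | `Σ (i−μ)² p(i,j)` |
| mean | `μ` |
| correlation | `Σ (i−μ)(j−μ) p(i,j) / σ²` |
| energy | `Σ p²` |
| homogeneity | `Σ p / (1+(i−j)²)` |
| mean sum | `Σ k p_{x+y}(k)` |
| entropy sum | `−Σ p_{x+y} log₂ p_{x+y}` |
| variance sum | `Σ (k − mean sum)² p_{x+y}(k)` |

Features are computed per `(d, θ)` matrix and averaged; per-subject values
are the mean over the 12 standard scan zones. The diagnostics layer
computes the empirical ROC curve per feature (trapezoidal AUC), the Youden
`J = sensitivity + specificity − 1` optimal cut-off, bootstrap comparison
of paired AUCs (2000 replicates), fourfold cross-validated classification
error of the Youden rule, and inter-observer agreement via the two-way
absolute-agreement ICC(2,1) and Cronbach's α.

Because no patient images are distributed, a synthetic module generates
(a) speckled texture phantoms for the three pleural-line classes (healthy,
CPE, ARDS) and (b) per-subject feature draws from the published per-group
means and SDs (8 ARDS, 16 CPE subjects), so the whole chain runs end to
end out of the box.

## Worked example

Extract features from an ARDS-like phantom with a rectangular ROI:

```python
from pleuratex import (PhantomSpec, generate_phantom, analyze_frame,
                       GlcmConfig, RoiShape)

frame = generate_phantom(PhantomSpec.for_class("ards", seed=7))
roi = RoiShape("rectangle", [(20, 4), (80, 123)])
features = analyze_frame(frame, roi, GlcmConfig())
print(f"{features.correlation:.4f}  {features.contrast:.4f}")
# 0.6999  4.3989
```

The high correlation (0.70) reflects the large patches of uniform grey in
the ARDS-like texture; contrast (4.40, in squared level units) is low for
the same reason. Then score a simulated 24-subject cohort on one feature:

```python
from pleuratex import simulate_group_features, roc_curve, cv_error

scores, labels = simulate_group_features(None, "homogeneity", seed=42)
res = roc_curve(scores, labels, positive="ARDS", seed=42)
err = cv_error(scores, labels, positive="ARDS", k=4, seed=42)
print(f"AUC {res.auc:.3f}  cutoff {res.cutoff:.3f} "
      f"sens {res.sensitivity:.3f} spec {res.specificity:.3f}  CV err {err:.3f}")
# AUC 0.953  cutoff 0.597 sens 0.875 spec 1.000  CV err 0.125
```

Homogeneity above 0.597 calls a subject ARDS; on this simulated cohort
that rule reaches AUC 0.953 with 87.5 % sensitivity and 100 % specificity,
and misclassifies 12.5 % of subjects under fourfold cross-validation.

The same chain is scriptable from the shell:

```bash
pleuratex phantom --class ards --seed 1 --out ards.png
pleuratex extract --input manifest.json --out features.csv
pleuratex aggregate --in features.csv --groups groups.csv --out subjects.csv
pleuratex roc --in subjects.csv --positive ARDS --out roc.json
pleuratex simulate --n 100 --seed 1 --out sim.csv
```

Extraction also composes with scikit-learn:
`GlcmTextureTransformer` is a `TransformerMixin` mapping a list of
`(frame, roi)` pairs to an `(n, 12)` feature matrix, and
`YoudenCutoffClassifier` is the threshold classifier used for the CV error.

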