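# Methods

## The measurement

The quantity of interest is the second-order texture of a small region of
a B-mode lung-ultrasound frame containing the pleural line. First-order
statistics (the grey histogram) cannot separate a bright speckled pleural
line from an inhomogeneously deranged one; co-occurrence statistics can,
because they are sensitive to the *joint* distribution of grey levels at a
fixed displacement.

A frame is an 8-bit greyscale image (values 0–255, row-major, origin at
the top-left). Grey values are quantized to `Ng` uniform levels by
`level = grey · Ng / 256` (floor), over the fixed 0–255 range rather than
the per-image min–max: per-image rescaling would make the level-valued
features (`mean`, `mean_sum`) incomparable across frames and subjects,
which is precisely the comparison the analysis needs. The default
`Ng = 16` balances computation against preservation of detail; values up
to 64 change little.

For each distance `d ∈ {1, 2, 3, 4}` (pixels along the displacement axis)
and direction `θ ∈ {0°, 45°, 90°, 135°}`, the co-occurrence matrix counts
every ordered pixel pair `(a, a + offset)` whose two pixels both fall
inside the ROI mask, incrementing `(i, j)` and `(j, i)` symmetrically.
The offsets are `0° → (0, d)`, `45° → (−d, d)`, `90° → (−d, 0)`,
`135° → (−d, −d)` in `(row, col)` with row increasing downward; under
symmetric accumulation the sign convention is unobservable (`θ` and
`θ + 180°` give identical matrices). Normalization divides by the realized
pair count — ROIs are irregular polygons, so no nominal count exists.
Note that some GLCM implementations (e.g. scikit-image) measure `d` as a
rounded Euclidean distance on the diagonals; here `d` is the pixel count
along the displacement axis, so the diagonal offset at `d` is `(±d, ±d)`.

## Features

Twelve Haralick-style features are computed from each normalized symmetric
matrix on the quantized level scale (not rescaled to 0–255); the README
table lists the formulas. Conventions that needed fixing:

* **Entropy base.** Both entropies use `log₂` (bits); any base is a
  constant rescaling, base 2 is declared for reproducibility.
* **Sum variance.** Computed about the sum mean `Σ k p_{x+y}(k)` — the
  dispersion of the level-sum histogram — not about the sum entropy, a
  well-known transcription accident in older feature lists.
* **Undefined correlation.** On a constant ROI the marginal SD is zero and
  correlation carries no information; it is recorded as NaN and excluded
  from downstream averages, never coerced to 0 or 1. All other features
  remain defined.
* **Cluster shade sign.** Positive when mass sits above the marginal mean
  on the `i + j` axis — bright clusters on a darker background; negative
  for dark clusters on a brighter background. This sign convention is what
  the phantom tests assert.

## ROI handling

ROIs arrive as a rectangle (two opposite corners, closed interval) or a
polygon (≥ 3 vertices, non-convex allowed — a ROI tracing a bending
pleural line usually is). Polygon rasterization uses the pixel-centre
even–odd rule with boundary pixels counted inside: the simplest convention
that is exactly testable against a per-pixel oracle. Coordinates are
0-based `(row, column)`. Frame selection and ROI placement are operator
inputs, not algorithms: the package deliberately contains no pleural-line
detector.

## Per-frame and per-subject aggregation

Features are computed per `(d, θ)` matrix — 16 matrices by default — and
averaged at the *feature* level (NaN correlations excluded). Averaging the
four directional matrices first (`averaging="matrix"`) is supported as an
option; with symmetric matrices the two differ only through the
nonlinearity of the features, and feature-level averaging is the default
because a single value per feature per frame is the quantity carried
forward. Whether to average over distances 1–4 or fix a single `d` is
configurable; the default averages, since all four distances are deemed
informative.

Per subject, features are averaged over the available scan zones (12
standard zones: left/right × anterior/lateral/posterior × upper/lower, one
representative still frame each). Subjects with fewer than 12 zones are
averaged over what they have, with `n_zones` reported. Zone records are
sorted before summation so the aggregate is bit-reproducible under record
shuffling.

## Diagnostics

* **ROC/AUC.** Empirical ROC over all distinct thresholds, trapezoidal
  AUC; with ties counted half this equals the normalized Mann–Whitney U
  statistic, which the tests exploit as an independent oracle. Direction
  is chosen per feature so AUC ≥ 0.5.
* **Youden cut-off.** Maximizes `J = sens + spec − 1` over midpoints
  between adjacent distinct scores; ties on `J` break toward higher
  sensitivity, then the lower cut-off. Midpoints and tie-breaks are
  declared conventions to make the cut-off deterministic.
* **AUC confidence intervals.** Stratified bootstrap percentile (2000
  replicates, seeded) by default; a DeLong placement-value normal interval
  is available where the bootstrap is too slow (e.g. 10⁵ subjects).
* **Paired AUC comparison.** Stratified bootstrap of subjects (both
  features resampled together), two-sided p from the normal approximation
  of the ΔAUC distribution. Stratification keeps both classes in every
  replicate even at n = 8 + 16. Identical features give p = 1 exactly.
* **CV error.** Stratified fourfold cross-validation of the Youden
  threshold rule (the only classifier in play, since accuracy is reported
  per single feature); error pooled over folds. A minority class smaller
  than the fold count degrades to leave-one-out with a warning.
* **Agreement.** ICC(2,1) — two-way random effects, absolute agreement,
  single measure — from the ANOVA mean squares, with the F-based
  confidence interval; Cronbach's α from rater variances versus the
  variance of subject sums. Zero between-subject variance yields ICC 0
  with a warning.

## Synthetic data

Two generators define the test conditions.

**Feature simulator.** Per-subject feature values are drawn from
independent Gaussians with the published per-group means and SDs
(8 ARDS, 16 CPE subjects). Normality is the minimal generative assumption
available from summary statistics; no between-feature covariance is
published, so none is imposed. Draws outside a feature's theoretical range
(correlation > 1, energy < 0, …) are clipped and the clipped fraction
logged; at the published means/SDs the clipped mass is far below 1 % and
does not move the AUCs at the tested tolerance. Under this model the
empirical AUC converges to the binormal closed form
`Φ(|μ₁−μ₂| / √(σ₁²+σ₂²))`, which is how the simulator is validated: at
10⁵ subjects per group the published AUROCs of contrast (0.891), cluster
shade (0.898), entropy (0.867), homogeneity (0.965) and entropy sum
(0.590) are recovered within ±0.015. The remaining published AUROCs
(correlation 1.000, mean 0.992, mean sum 0.992, variance sum 0.984,
energy 0.816, variance 0.711) are *not* binormal-consistent with their own
group means/SDs — they reflect the particular 24-subject sample — and
cannot be reproduced from summary statistics; the simulator makes no
attempt to.

**Phantoms.** 128×128 scenes emulating the three pleural-line texture
classes: sparse bright discs (level 220) on a darker background (100) for
healthy; sparse dark discs (60) on a brighter background (170) for CPE;
large connected patches of uniform dark grey (70 on 150), obtained by
thresholding a Gaussian random field smoothed at 8 px, for ARDS. Speckle
is multiplicative unit-mean Rayleigh noise blended at strength 0.35
(reduced to a quarter inside the ARDS patches, whose defining property is
uniformity). Disc density 0.04 of the frame area, radius 3 px. Generation
is pure: a spec (including its seed) maps to identical bytes. Only sign
and ordering claims are asserted on phantoms — positive shade for
healthy, negative for CPE, higher correlation for ARDS than CPE — never
feature magnitudes: the phantoms are texture surrogates, not ultrasound
simulations (no PSF, attenuation, or scan conversion), and passing them
shows the feature semantics, not clinical performance. Equally, the
Gaussian simulator reproduces subject-level distributions only; it says
nothing about zone-level variance or between-feature dependence in real
cohorts.

## Problem sizes and numerics

The test suite and the acceptance script use: 200 random frames up to
32×32 for oracle equivalence (entrywise 1e−12); 100 random matrices for
the reflection property (1e−9); 10⁵ subjects per group for AUC recovery
(±0.015); 100 seeded phantom replicates per class (≥ 95 must satisfy each
sign/ordering claim); 2000 subjects for the permuted-label CV null
(0.5 ± 0.05); 200 simulated 24-subject cohorts for the study-scale CV
error. GLCM normalization tolerates 1e−9 on the sum; matrix symmetry is
exact by construction (`counts + countsᵀ`). CSV feature tables are written
with 17 significant digits, so read-back round-trips beyond 12 significant
digits and repeated extraction is byte-identical.

## Known limitations

* Single-frame analysis per zone by default, matching the acquisition
  protocol's single representative still per clip; extra frames in a zone
  are collapsed into the zone mean during aggregation if supplied.
* No automatic pleural-line detection, overlay stripping, or "most
  pathological area" selection — all operator inputs.
* DICOM support covers 8-bit monochrome and colour (luma-converted)
  frames; deeper pixel formats are accepted only with rescale information.
* The diagnostic layer is single-feature; no multivariate classifier is
  provided because per-feature accuracy is the reported quantity.
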