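# Methods

This note records the models, conventions and design choices behind
`neolus`, in the order the pipeline applies them.

## Region of interest

The ROI upper limit is a pleural trace: an ordered polyline of (row, column)
points with strictly increasing columns, linearly interpolated to every
spanned column. Columns outside the trace span are excluded. The mask starts
**one pixel below** the interpolated trace in each column — the trace is
placed at the top edge of the pleural band, so the bright pleural pixels
themselves fall inside the ROI.

Constant area is enforced by a rectangle-under-curve construction: each
spanned column receives the same depth `d = ceil(area / n_columns)` of
pixels below the trace, then the excess `n_columns·d − area` is trimmed from
the deepest row, rightmost columns first. The achieved area therefore equals
the requested area (50 000 or 100 000 px by default) exactly whenever the
frame is deep enough; otherwise a capacity error reports the maximum
achievable area. Because both ROI sizes share the trace and differ only in
depth, the large ROI strictly contains the small one — the extra pixels all
come from deeper lung.

For synthetic frames an automatic trace is provided: per column, the first
row whose vertically median-smoothed intensity crosses 60 % of the column
maximum (the pleura is the shallowest bright structure, so a first-crossing
rule is robust to bright subpleural fields and speckle outliers), median
smoothed over 15 columns. It is a fixture-support heuristic, not a clinical
pleural-line detector.

## First-order statistics

Native 8-bit histogram (256 integer bins, no re-binning), arithmetic mean,
and **population** variance (divide by *n*; at ROI sizes of 50 000 px the
sample/population distinction is negligible, but the convention is pinned
for exact tests). The eight per-view ROI means of a patient are averaged
into the gray-scale mean intensity score.

## Co-occurrence texture features

The GLCM for offset (Δr, Δc) counts **ordered** pairs (p, p + offset) whose
members both lie inside the ROI mask, then normalizes to a distribution
P<sub>ij</sub>. No symmetrization and no averaging over directions: the
horizontal (0, +2) and vertical (+2, 0) matrices are kept separate and each
yields 22 features, concatenated horizontal-first into the 44-vector in the
fixed order group 1, group 2, group 3 (see `glcm.FEATURE_ORDER`).

Conventions, chosen once and applied everywhere:

* **Gray levels** are 0-based after quantization `level = floor(gray·L/256)`;
  L defaults to 256 (native 8-bit, i.e. no re-quantization) and may be any
  divisor of 256. With 0-based levels the two printed contrast forms CO1
  (difference-distribution moment) and CO2 (direct sum) are algebraically
  identical, as are the two correlation forms C1 and C2 — the tests verify
  both identities.
* **Entropies** use the natural logarithm with 0·log 0 ≡ 0. The log base
  only rescales entropy-type features.
* **Variance V** is Σ (i − μ)² P with μ the mean gray level under P, taken
  as (μ<sub>x</sub> + μ<sub>y</sub>)/2 — the average gray level over both
  pair members. For the nearly symmetric marginals of real ROIs the choice
  of μ is immaterial; it is pinned here for reproducibility.
* **Sum variance SV** uses the **sum entropy** SH inside the square,
  Σ (n − SH)² s<sub>n</sub>, following the printed formula rather than the
  sum-average variant.
* **MCC** is the second-largest-modulus eigenvalue (real part) of
  Q<sub>ij</sub> = Σ<sub>k</sub> P<sub>ik</sub>P<sub>jk</sub> /
  (p<sub>x</sub>(i) p<sub>y</sub>(k)), rows/columns with zero marginal
  skipped; no square root is applied. Q is row-stochastic, so its spectrum
  lies in the unit disk and the leading eigenvalue is 1.
* **IC1** = (H − H1XY)/max{HX, HY}; **IC2** = √(1 − exp(−2(H2XY − H))) with
  a negative radicand clamped to 0.
* **Degenerate inputs** never produce non-finite values: zero marginal
  variance maps C1 = C2 = 0; a single-level image gives zero entropies,
  energy 1, MCC 0, IC1 0 (zero marginal entropy), IC2 0.

Group membership used by the per-group analyses: group 1 (classical, 10) =
{H, HO, D, CS, CP, AC, CO2, A, V, M}; group 2 (sum/difference, 7) =
{INV, CO1, SA, SH, DH, SV, DV}; group 3 (correlation, 5) =
{C1, C2, MCC, IC1, IC2}.

## Severity regression

Support-vector regression, RBF kernel, trained at frame level: each frame
inherits its patient's oxygenation index as target, and a **leave-one-
patient-out** fold structure guarantees that no frame of the evaluated
patient enters training. The held-out patient's frame predictions are
averaged into one per-patient prediction, mirroring the pooling used for the
mean-intensity score.

Hyperparameters (all config-exposed): C = 1, ε = 0.1 on the standardized
target scale — equivalently one tenth of the training targets' SD — and
γ = `scale` (1/(n_features·Var)). Feature standardization and target
z-scoring are fitted inside each training fold; zero-variance features map
to 0. Predictions are transformed back to mmHg.

ROC evaluation dichotomizes the **true** index (PaO₂/FiO₂ < 200 positive;
A-a > 150 mmHg positive) and uses the continuous LOPO predictions as scores;
PF predictions are negated first so that a higher score always indicates the
positive (worse) class. Direct scores whose orientation already increases
with severity (visual sum, mean intensity) are used unnegated. AUC is the
Mann–Whitney pair-counting estimator with ties counting ½.

A kernel smoother cannot extrapolate: for the one or two patients whose
index lies at the extreme of the cohort's range, the LOPO prediction shrinks
toward the training span and can miss the ε-tube tolerance even on
noise-free features. The recovery tests therefore assert the tube tolerance
on interpolation-regime patients and only directional shrinkage at the
extremes; rank-based summaries (Spearman, AUC) are unaffected.

**PCA sweeps** keep standardization and the PCA basis inside each training
fold (the basis is fitted once per fold at the largest k and truncated,
since leading components do not depend on how many are kept). The
explained-variance curve reported alongside is a descriptive fit on all
frames — a single curve, while the predictive sweep stays leakage-free.

## Clinical statistics

* PaO₂/FiO₂ in mmHg; A-a gradient = PA − PaO₂ with
  PA = FiO₂·(760 − 47) − PaCO₂/0.8 (sea-level barometric pressure minus
  water vapor; respiratory quotient 0.8). Negative gradients are returned
  as-is.
* Visual score: sum of the eight 0–3 view grades, range 0–24.
* Spearman ρ via average-rank ties with the t-approximation p-value; the
  95 % CI uses the Fisher z transform with SE = 1/√(n−3) — a standard choice
  when no CI method is otherwise specified.
* Cohen's κ is unweighted by default and computed primarily over frame-level
  grade pairs (600 in the default study), the natural unit for interobserver
  concordance; per-patient-sum κ is emitted as a secondary output, and
  linear/quadratic weighting is available behind a flag. The degenerate case
  p<sub>e</sub> = 1 (both raters constant and identical) is defined as κ = 1.

## Synthetic cohort generator

The generator defines the study conditions: 75 patients × 8 views (four
standard views per side) = 600 frames, 512×384 px, pleural line at 48 px.
Severity s ~ Uniform(0, 1) per patient drives everything:

* per-view grade = clip(round(3s + ε), 0, 3), ε ~ N(0, 0.5);
* FiO₂ = 0.21 + 0.59 s; PaO₂/FiO₂ = clip(400 − 280 s + N(0, 40), 50, 500);
  PaO₂ = ratio·FiO₂; PaCO₂ = clip(N(45, 7), 25, 80). These constants put the
  cohort mean PF near 260 with A-a rising steeply in s, spanning the
  clinically relevant ranges on both sides of the 200/150 cutoffs;
* two raters report the true grade with probability 1 − 0.05, otherwise ±1
  clipped to [0, 3], independently per rater and frame.

Grade renderers are qualitative emulations of the four sonographic
patterns: A-line reverberations at multiples of the pleural depth (grade 0),
4–8 well-spaced bright vertical streaks (grade 1), 10–16 overlapping wide
streaks (grade 2), a near-uniform bright field with darker consolidation
blobs under a jittered, irregular pleural band (grade 3). Renderer levels
are fixed so the expected subpleural mean is strictly increasing in grade.
Speckle is a multiplicative unit-mean Rayleigh factor blended by
σ (default 0.3), applied before clipping to [0, 255]; σ = 0 reproduces the
configured levels exactly.

One root integer seed drives a hierarchical per-patient/per-frame
`SeedSequence` stream, so cohorts are bit-reproducible and any single frame
can be regenerated from the seed recorded in the manifest.

**What the generator does not emulate:** curvilinear fan geometry, acoustic
wave physics, depth-dependent attenuation/gain, rib shadows, real pleural
irregularity, and — most importantly — the true covariance between
sonographic texture and physiology in sick neonates. Passing end-to-end
tests shows the pipeline recovers relationships *that the generator builds
in*, with the expected signs and usable effect sizes; it does not validate
the clinical effect sizes themselves, which require real data.

## Problem sizes and determinism

The test suite analyzes the full default cohort (600 frames) once per
session at the 50 000-px ROI and reuses the result across end-to-end checks
(~35 s); feature-layer oracle tests run on 8×8 images at L = 8 where a
brute-force double-loop reference is exact. The acceptance script analyzes
both ROI sizes on the 600-frame cohort in about two minutes on one CPU.
All randomness in package, tests and scripts descends from explicit integer
seeds; repeated runs are bit-identical.

## Known limitations

* The automatic pleural trace targets the synthetic renderer only; real
  images need manual traces (CSV polylines).
* L = 256 keeps native gray resolution but makes the GLCM sparse
  (≈100 K pairs over 65 K cells); entropy-type features are then close to
  their sampling ceiling and comparisons across very different ROI sizes
  should use equal pair counts or a coarser L.
* Only uncompressed grayscale DICOM transfer syntaxes are read.
* SVR hyperparameters are fixed defaults, not tuned; no nested model
  selection is performed.
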