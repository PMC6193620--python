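# neolus

Computer-assisted gray-scale quantification of neonatal lung ultrasound.

Lung ultrasound grades neonatal respiratory distress through artifacts —
A-lines in aerated lung, vertical B-lines in interstitial syndrome, coalescent
B-lines and subpleural consolidations as disease worsens. Clinicians rate each
view on a 0–3 visual scale; `neolus` implements the complementary quantitative
route: a region of interest (ROI) anchored to the hand-traced pleural line,
first-order gray statistics, second-order texture descriptors from the
gray-level co-occurrence matrix (GLCM), and a machine-learning severity
regression — evaluated against blood-gas oxygenation indices exactly as a
clinical validation study would.

## What it computes

For each 8-bit B-mode still frame:

* **ROI** — upper limit follows the pleural trace; lateral/bottom sides are
  drawn with square angles at constant area (50 000 or 100 000 px, enforced
  exactly by a bottom-row trimming rule).
* **First-order statistics** — 256-bin histogram, mean, population variance;
  the 8 per-view ROI means pool into a per-patient *gray-scale mean intensity
  score*.
* **GLCM texture** — the co-occurrence distribution P<sub>ij</sub> of
  gray-level pairs 2 px apart, horizontally and vertically. From each P: 22
  descriptors (entropy H, homogeneity HO, dissimilarity D, cluster shade/
  prominence, autocorrelation, contrast, energy, variance, maximum
  probability; sum/difference-distribution features INV, CO1, SA, SH, DH, SV,
  DV; correlation features C1, C2, MCC, IC1, IC2), giving a 44-dimensional
  per-frame vector.

Per patient, the clinical layer derives the oxygenation ratio PaO₂/FiO₂ and
the alveolar–arterial gradient A-a = PA − PaO₂ with
PA = FiO₂·(760 − 47) − PaCO₂/0.8, and evaluates:

* Spearman ρ (Fisher-z 95 % CI) of visual score and intensity score against
  both indices;
* Cohen's κ between two raters' frame-level grades;
* ROC/AUC at the PaO₂/FiO₂ < 200 and A-a > 150 mmHg cutoffs, both for the
  direct scores and for a support-vector regressor (RBF kernel) on the
  44-dim texture vectors with **leave-one-patient-out** cross-validation;
* per-feature-group AUC tables and PCA feature-reduction sweeps.

Because no public frame dataset accompanies this protocol, the package ships
a synthetic cohort generator (`neolus.cohort`) that renders the four severity
grades with Rayleigh speckle and couples grade to oxygenation through a
severity law, so the whole pipeline is testable end-to-end from a single seed.

## Worked example

```python
from neolus import (FrameSpec, generate_frame, auto_trace, build_roi,
                    extract_pixels, first_order_stats, feature_vector,
                    feature_names)

frame = generate_frame(FrameSpec(grade=2, seed=7))   # coalescent B-lines
trace = auto_trace(frame)                            # pleural line heuristic
roi = build_roi(trace, 50_000, frame.shape)
stats = first_order_stats(extract_pixels(frame, roi))
print(f"ROI area: {roi.achieved_area} px")
print(f"mean intensity: {stats.mean:.2f}  variance: {stats.variance:.2f}")

vec = feature_vector(frame, roi)                     # 44 values
names = feature_names()
for n in ("H_h", "CO2_h", "A_h", "C1_h", "CO2_v"):
    print(f"{n:6s} = {vec[names.index(n)]:.4f}")
```

prints

```
ROI area: 50000 px
mean intensity: 100.06  variance: 4779.79
H_h    = 8.5174
CO2_h  = 2485.6509
A_h    = 0.0005
C1_h   = 0.7402
CO2_v  = 1078.8988
```

The ROI holds exactly 50 000 pixels. A grade-2 frame has a mid-range mean
(between the dark grade-0 and bright grade-3 patterns) and high variance from
the bright streaks on a dark field. Entropy H ≈ 8.5 nats reflects the
speckle-spread co-occurrence distribution; horizontal contrast CO2 exceeds
its vertical counterpart because the vertical B-line streaks make gray levels
change faster across columns than along them; C1 ≈ 0.74 shows the strong
2-px-lag correlation typical of speckle texture.

A full synthetic study from the shell:

```bash
neolus run --n-patients 75 --seed 0 --out results/run0
neolus simulate --n-patients 5 --seed 1 --out cohort5   # frames + manifest
neolus evaluate --manifest cohort5/manifest.csv --out results/eval5
```

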