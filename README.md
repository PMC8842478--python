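# kcpachy

Corneal thickness profiling and keratoconus (KC) staging from segmented
anterior-segment OCT (AS-OCT) B-scans — normal-line pachymetry over a 6 mm
region of interest, 20-zone cohort statistics, thickness ectasia indices and
LDA-based stage discrimination — exercised end to end on synthetic corneal
phantoms with analytically known ground truth.

## The problem

Keratoconus progressively thins and steepens the cornea, with the thinning
concentrated slightly temporal and inferior of the pupil centre.  Staging the
disease from cross-sectional AS-OCT images requires (1) accurate corneal and
epithelial boundaries, (2) a thickness measurement that respects the corneal
geometry, and (3) cohort-level statistics that expose how the thickness
distribution changes with severity.  This package implements the measurement
and analysis stack downstream of segmentation:

* **Phantoms** (`kcpachy.phantom`) — a synthetic cohort generator: a circular
  anterior surface, thickness profiles `T(s)` and `E(s)` (cornea, epithelium)
  along arc position `s` built as a peripheral baseline minus a Gaussian
  thinning cone, with scarring-stage epithelial fluctuations.  The interface
  and posterior boundaries are constructed by stepping `E` and `T` along the
  inward anterior normal, so the generator's thickness functions are exact
  ground truth for normal-line measurement.  Stage-group central thickness is
  calibrated to a clinical five-group cohort (normal, mild, moderate, severe,
  scarring KC; 118/134/239/153/71 eyes).
* **Boundary extraction** (`kcpachy.boundaries`) — subpixel anterior /
  epithelium–stroma / posterior traces from 3-class label masks (exact, edges
  on half-integer pixel rows) or from grayscale renders via axial-gradient
  extrema with parabolic refinement.  Either path fills the same
  `BoundarySet` contract a learned segmenter would.
* **Pachymetry** (`kcpachy.pachymetry`) — pupil-centre reference at the scan
  centre, 40 sample points every 0.15 mm of arc over the ±3 mm ROI, thickness
  as the distance from the anterior surface to the target boundary along the
  local inward surface normal (quadratic-fit normal, ray marching +
  bisection).  Right-eye horizontal profiles are mirrored to a common
  temporal-negative orientation.
* **Zone statistics** (`kcpachy.stats`) — the 40 samples pair into 20 zones;
  per zone: group means with t-based 95% CIs, one-way ANOVA across the five
  groups, Welch two-sample t-tests, and an OLS trend of thickness on the
  stage ordinal.
* **Staging** (`kcpachy.staging`) — per eye, four thickness ectasia indices
  (max/min over the 40 ROI samples: EEI_H, EEI_V, CEI_H, CEI_V); a two-class
  Fisher LDA per KC stage against normal, scored by in-sample ROC/AUC.
* **Evaluation** (`kcpachy.evaluation`) — Dice, IoU, sensitivity,
  specificity and the indirect thickness-error metric (mean |Δthickness| in
  μm) against reference masks and profiles.

## Worked example

```python
import numpy as np
import kcpachy as kp

spec = kp.make_phantom_spec("severe", "OS", "H", seed=42)
truth = kp.boundaries_from_spec(spec)
bset = kp.trace_from_mask(kp.rasterize_masks(truth))
epi, cor = kp.measure_profile(bset)

s = cor.positions
true_cor = np.asarray(kp.analytic_thickness(truth, s, "cornea"))
i = int(np.argmin(cor.values))
print(f"min corneal thickness {cor.values[i]:.1f} um at {s[i]:+.3f} mm")
print(f"max |measured - analytic| = {np.abs(cor.values - true_cor).max():.2f} um")
```

prints

```
min corneal thickness 486.5 um at -0.375 mm
max |measured - analytic| = 1.56 um
```

i.e. the thinnest point lands at the generated cone (true centre −0.386 mm,
recovered at the nearest 0.15 mm sample), and the measured profile agrees
with the analytic ground truth to about half of one ~3 μm pixel — the
residual is mask rasterization, not the measurement.

The scripts in `examples/` walk through each capability (phantom + mask
generation, pachymetry vs. truth, zone statistics, ectasia-index staging,
segmentation evaluation); each prints the numbers it computes with a line on
what they mean.  On a 30-eyes-per-stage cohort the staging example prints

```
       mild vs normal: AUC = 0.583
   moderate vs normal: AUC = 0.764
     severe vs normal: AUC = 0.819
   scarring vs normal: AUC = 0.977
```

— discrimination improves monotonically with severity, because deeper cones
inflate the max/min thickness ratios.

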