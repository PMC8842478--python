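# Methods

## Coordinate and geometry conventions

B-scans live on a pixel grid with 0-based indices, pixel centres at integer
coordinates, and y increasing downward (into tissue).  Physical coordinates
are index × pitch in μm.  The default grid is 2648 × 640 pixels covering
8 mm × 1.933 mm, i.e. ~3.02 μm nearly isotropic pixels.  Boundaries extracted
from label masks are placed on **pixel edges** (half-integer rows): the
anterior boundary of a band whose first tissue pixel is row *r* sits at
*r* − 0.5.  This convention makes an *n*-pixel band exactly *n*·pitch thick
and keeps mask-path thickness free of systematic half-pixel bias.  The
subpixel convention is a package choice; all internal comparisons use it
consistently.

## Phantom model

Each synthetic scan is generated from a `PhantomSpec`:

* anterior surface: circular arc, radius ~7.8 mm (drawn N(7800, 120) μm,
  clipped to [7300, 8300]), apex 150 μm below the top image edge at the
  central column;
* corneal thickness along arc position *s* (mm from the scan centre):
  `T(s) = P − (P − A)·exp(−(s − s₀)²/(2σ²))` with peripheral baseline `P`,
  apex thickness `A`, cone centre `s₀` and width `σ`; epithelial thickness
  `E(s)` analogous with peripheral 52 μm;
* the epithelium–stroma interface and posterior surface are the anterior
  curve offset by `E(s)` and `T(s)` along the inward anterior normal.  For a
  circle the normal is radial, so the offset curves are concentric-like and
  a normal-line measurement from the anterior surface recovers `T` and `E`
  **exactly** — the analytic profiles are a true oracle for the pipeline.

Stage-group calibration (normal / mild / moderate / severe / scarring):

| parameter | values | rationale |
|---|---|---|
| apex corneal mean (μm) | 504.5 / 496.0 / 475.7 / 455.3 / 376.1 | clinical group means near the thinnest zone |
| apex corneal s.d. (μm) | 39.5 / 34.0 / 37.2 / 49.6 / 55.0 | chosen so simulated 95% CIs at the clinical group sizes match the reported CI widths |
| apex epithelial mean (μm) | 48.9 / 48.2 / 43.7 / 40.3 / 46.9 | clinical group means |
| apex epithelial s.d. (μm) | 5.7 / 6.1 / 6.6 / 7.1 / 15.0 | as above |
| peripheral corneal (μm) | 620 / 586 / 570 / 552 / 525 | KC corneas are thinner across the whole profile, not only at the cone; values chosen once so the group ordering is monotone at every zone distance (see below) |
| cone σ (mm) | 1.5 / 1.2 / 1.0 / 0.8 / 0.8 | focal thinning narrows with severity; normal eyes get a broad, gentle central dip |
| cone centre (mm) | N(−0.45, 0.10), clipped [−0.8, −0.1] | thinning sits ~0.5 mm temporal (horizontal) / inferior (vertical) of the pupil centre, putting the minimum in zone 9 |

A constant peripheral baseline for all stages cannot reproduce the clinical
pattern: as the cone narrows with severity, all profiles converge at the ROI
periphery and the broad normal-stage dip would make *normal* eyes the
thinnest group in the outermost zones, flipping the peripheral trend sign.
The stage-dependent baseline encodes the global (not only focal) thinning
seen clinically and was fixed analytically, by checking group ordering
pointwise across the ROI, before any cohort simulation.  The peripheral
*epithelial* baseline stays common (52 μm) across stages: with the narrowing
cone this reproduces the clinically observed *positive* epithelial trend
slopes in the peripheral zones.

Scarring-stage epithelium adds a smooth, seeded, zero-mean fluctuation to
`E(s)`: white noise on a 0.05 mm grid, Gaussian-smoothed to ~0.5 mm
correlation length, rescaled to ~6 μm amplitude — irregular epithelium over
a grossly thinned stroma.  Eye-level draws (apex thickness, radius) are
shared between the two meridians of an eye; cone placement is drawn per
meridian (the scans are independent 1-D slices; no 3-D cornea is modelled).
Right-eye (OD) horizontal specs flip the cone-offset sign so that the
standard OD-mirroring step lands the cone temporally.

Everything is a pure function of `(stage, laterality, meridian, seed)`;
cohort generation derives per-eye seeds from a single cohort seed.

### What the phantoms do not capture

No OCT physics (speckle statistics beyond a gamma multiplicative model, no
refraction, no axial PSF), no 3-D corneal shape, no hydrops or Descemet
rupture morphology, no segmentation failures of the kind a network produces
(the mask path is exact by construction).  Passing tests therefore validate
the *measurement and statistics*, and bound only rasterization-level
segmentation error — they say nothing about boundary accuracy on real
images.

## Boundary extraction

*Mask path*: per column, the anterior/interface/posterior edges are read off
the label bands at half-integer rows; interior columns missing a class are
linearly interpolated, leading/trailing ones truncated; any column violating
background → epithelium → stroma → background ordering raises.

*Image path*: columns of the render are Gaussian-smoothed axially (σ=2 px)
and laterally (σ=4 px; speckle is uncorrelated across columns), and
boundaries are taken at axial-gradient extrema — the first strong
dark→bright peak (anterior), the strongest bright→dark below it (posterior),
and the strongest rise in the plausible epithelium band between them
(interface) — with parabolic subpixel refinement and a 15-column median
filter.  Columns whose best gradient falls below threshold are interpolated;
extraction fails if more than half the columns do.  On default speckled
renders the 95th-percentile boundary error is under one pixel.

## Pachymetry

The pupil-centre reference is the anterior point at the central image column
(scans are pupil-fixated).  Sample positions are **arc length** along the
anterior trace — matching a spacing defined "along the surface" — at the
centres of forty 0.15 mm bins spanning [−3, +3] mm: −2.925 … +2.925 mm.
This fencepost choice yields exactly 40 symmetric points and places zone 9
(samples 17–18) at −0.525/−0.375 mm, bracketing the ~0.45 mm temporal
thinning locus.  Chordal spacing would differ by <1% over this ROI.

At each sample the local normal comes from a quadratic fit of y(x) over
±300 μm; thickness is found by marching `p + t·n` in 0.5 μm steps to the
first sign change of depth relative to the (linearly interpolated) target
trace, refined by bisection below 0.1 μm, capped at 2000 μm.  Ties (multiple
intersections) resolve to the first along the ray.

Traces are moving-average smoothed (31 columns ≈ 94 μm) before arc-length
and normal computation: pixel-edge quantization otherwise inflates polyline
arc length (each ±1-pixel stair step adds length) and tilts fitted normals.
The window flattens a corneal-scale circle by <0.1 μm.  With it, the
mask-path measurement stays within ~2.4 μm of analytic truth across all
stages and seeds tested — within the one-pixel (~3 μm, bound 4 μm) target.

OD horizontal profiles are mirrored (value sequence reversed on the fixed
symmetric grid) to the common left-eye, temporal-negative orientation before
any cohort statistics; the operation is an involution.

## Statistics

Zone *j* (1-based, 1..20) averages samples 2j−1 and 2j; zone 1 is most
temporal/inferior.  Group summaries use t-based CIs (mean ±
t₀.₉₇₅,ₙ₋₁·s/√n).  Group comparison uses Welch's t-test — the scarring
group's variance is clearly larger than the others', so pooling would be
wrong.  The stage trend is OLS of thickness on the ordinal coding
0=normal … 4=scarring (equally spaced, scarring included).  No
multiple-testing correction is applied — p-values are reported raw,
matching the convention of reporting per-zone raw significance.  Each eye is
one independent unit.  ANOVA/t/CI/OLS computations are scipy.stats calls
behind this module's interface.

## Staging

Ectasia indices are max/min over the profile's 40 ROI samples (not the full
8 mm scan width; configurable by passing different profiles).  The
discriminant is two-class Fisher LDA: `w ∝ Σ_pooled⁻¹(μ_stage − μ_normal)`
with the offset centring the score at the midpoint of projected class means;
a ridge of `λ·tr(Σ)/4` with λ=10⁻⁶ guards the near-singular covariance of
four strongly correlated ratio features.  ROC is an in-sample threshold
sweep (no cross-validation, mirroring the simple screening protocol); ties
count ½, so AUC equals the Mann–Whitney concordance probability.  Note the
in-sample protocol inflates the permutation-null AUC above 0.5 by
~√(d/n); at 4 features and 100 eyes/group the null centres near 0.57.

On the default cohort the four AUCs come out ~0.71 / 0.79 / 0.88 / 0.99
(mild → scarring; seed-dependent at the third digit), monotone in severity.

## Evaluation

Dice, IoU, sensitivity and specificity are pixel counts for a target class —
epithelium alone, or "cornea" = epithelium ∪ stroma.  Specificity uses the
full image grid as the negative universe (configurable in principle; the
full-grid convention is the default because the background dominates and is
part of the segmentation task).  Per-image metrics are averaged within
(tissue, group) cells — per-image-then-average, not pooled pixels.  The
indirect metric is the mean absolute difference between candidate and
reference 40-point profiles, in μm.

## Problem sizes and numerical choices

The default study runs the full five-group cohort (715 eyes, 1430 scans) at
full resolution through the mask path in under a minute; the acceptance
script adds a 10-eye image-path evaluation.  Property tests use 2000
replicates (ANOVA type-I error, CI coverage) and 50 seeds × 5 stages
(measurement-oracle equivalence).  Degenerate inputs raise dedicated errors
rather than returning NaN: empty masks, ordering violations, insufficient
ROI coverage, rays that miss the target boundary, single-ordinal trends,
zero-variance ANOVA, identical LDA classes, single-class ROC.

## Known limitations

* The generator's peripheral values and cone widths are design choices, not
  fitted quantities; only the stage-group central thickness (and the CI
  widths at the clinical group sizes) are calibrated to clinical values.
* Boundaries are single-valued in x (valid for the central ≤6 mm cornea at
  this field of view, not for a full limbus-to-limbus scan).
* The learned segmentation stage is intentionally out of scope; the image
  path is a classical stand-in behind the same `BoundarySet` contract.
* AUCs are in-sample; with ~4 features and ≥71 eyes per group the optimism
  is modest but nonzero (see above); a cross-validated variant would shift
  values down slightly.
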