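"""Normal-line pachymetry on a phantom, checked against analytic truth.

Traces boundaries from the label mask, measures the 40-point epithelial and
corneal thickness profiles along anterior-surface normals over the 6 mm ROI,
and compares every sample with the generator's exact thickness functions.
"""

import numpy as np

import kcpachy as kp

spec = kp.make_phantom_spec("severe", "OS", "H", seed=42)
truth = kp.boundaries_from_spec(spec)
bset = kp.trace_from_mask(kp.rasterize_masks(truth))

epi, cor = kp.measure_profile(bset)
s = cor.positions  # signed mm from the pupil-centre reference

true_cor = np.asarray(kp.analytic_thickness(truth, s, "cornea"))
true_epi = np.asarray(kp.analytic_thickness(truth, s, "epithelium"))

i_min = int(np.argmin(cor.values))
print(f"corneal thickness: min {cor.values[i_min]:.1f} um at {s[i_min]:+.3f} mm "
      f"(true cone center {spec.cone_center_offset:+.3f} mm)")
print(f"epithelial thickness at centre: {epi.values[20]:.1f} um")
print(f"max |measured - analytic|: cornea {np.abs(cor.values - true_cor).max():.2f} um, "
      f"epithelium {np.abs(epi.values - true_epi).max():.2f} um")
print("(~one 3 um pixel: the residual is mask rasterization, not the measurement)")
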