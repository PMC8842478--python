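"""Generate a synthetic keratoconic B-scan phantom and its label mask.

Builds a severe-stage cornea with a known Gaussian thinning cone, rasterizes
the 3-class mask (background/epithelium/stroma) on the default 2648 x 640
grid (~3 um pixels), and writes it as PNG + JSON sidecar.
"""

import numpy as np

import kcpachy as kp
from kcpachy.io import write_mask

spec = kp.make_phantom_spec("severe", laterality="OS", meridian="H", seed=42)
truth = kp.boundaries_from_spec(spec)
mask = kp.rasterize_masks(truth)

print(f"stage={spec.stage.name}  cone center {spec.cone_center_offset:+.2f} mm, "
      f"sigma {spec.cone_sigma:.2f} mm")
print(f"apex corneal thickness   {spec.apex_corneal_thickness:7.1f} um")
print(f"peripheral corneal value {spec.peripheral_corneal_thickness:7.1f} um")
print(f"thickness at cone center {truth.corneal_thickness(spec.cone_center_offset):7.1f} um"
      "  (equals the apex value by construction)")

counts = np.bincount(mask.labels.ravel(), minlength=3)
print(f"mask pixels: background {counts[0]}, epithelium {counts[1]}, stroma {counts[2]}")

write_mask(mask, "scratch_mask.png", stage=spec.stage.name, meridian=spec.meridian)
print("wrote scratch_mask.png (+ .json sidecar with pixel geometry)")
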