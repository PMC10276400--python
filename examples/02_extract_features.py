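"""Calibrate physical scale from the 30 cm reference plate and extract the
92-trait catalog for one plant (one top view + six side views, averaged).

The printed traits are the six used throughout the regression stage: convex
area (CA1, cm^2), projected area (PA1, cm^2) and compactness (SC = PA1/CA1)
for each view prefix (S = side mean, T = top).
"""

from leafpheno import (
    SceneConfig,
    aggregate_views,
    calibrate_scale,
    extract_view,
    generate_scene,
)
from leafpheno.synth import SIDE_ANGLES, render_view

config = SceneConfig(width_px=256, height_px=256)
scene = generate_scene(config, day=60.0, seed=3)
calib = calibrate_scale(scene.plate_mask, config.plate_diameter_cm)
print(f"scale: {calib.cm_per_px:.4f} cm/px (true {config.cm_per_px:.4f})")

rgb, mask = render_view(scene, "top")
top = extract_view(rgb, mask, calib, "T")
sides = []
for angle in SIDE_ANGLES:
    rgb, mask = render_view(scene, "side", angle)
    sides.append(extract_view(rgb, mask, calib, "S"))

vector = aggregate_views(top, sides)
print(f"catalog size: {len(vector)} traits")
for name in ("SCA1", "SPA1", "SSC", "TCA1", "TPA1", "TSC", "SMW2_5"):
    print(f"  {name:7s} = {vector[name]:9.3f}")
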