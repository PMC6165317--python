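"""Segment the central tooth/tab of a rendered intraoral frame.

The pipeline converts the RGB frame to the tooth-emphasising grayscale
G - |R - G| (gum is much redder than tooth, so it collapses toward zero),
finds Canny edges, thresholds at the mean gray of the edge area, labels the
connected components, and keeps the one nearest the image center.
"""

import numpy as np

from shadematch import default_palette, render_scene, segment_target
from shadematch.colorspace import delta_e, lab_to_rgb, rgb_to_lab
from shadematch.synthetic_data import three_teeth_spec

palette = default_palette(seed=0)
tab = "3M2"
tab_rgb = lab_to_rgb(palette[tab])

# a three-teeth scene with pixel noise and a small specular glare patch
spec = three_teeth_spec(tab_rgb, noise_sd=2.0, glare=True)
image, truth_mask = render_scene(spec, tab_rgb, np.random.default_rng(0))

region, mean_rgb = segment_target(image, glare_exclude=True, glare_percentile=93)
iou = (region.mask & truth_mask).sum() / (region.mask | truth_mask).sum()
recovered = rgb_to_lab(mean_rgb)

print(f"components found: {region.label_count}, selected label {region.selected_label}")
print(f"IoU with the true tab rectangle: {iou:.3f}")
print(f"painted   Lab: {palette[tab].to_array().round(2)}")
print(f"recovered Lab: {recovered.to_array().round(2)}")
print(f"dE(recovered, painted) = {delta_e(recovered, palette[tab]).delta_e:.2f}")
print("IoU near 1 and dE well under 2 mean the central tab was isolated "
      "cleanly despite gum, neighbors, noise and glare.")
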