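"""Oil-Red-O lipid coverage by random-ROI sampling.

Renders a synthetic stained section (30 mm bark→pith at 20 µm/px) with
1% droplet coverage, thresholds the red stain and estimates areal
coverage with the standard sampling plan: 50 random 0.25-mm² ROIs in
each of ten 3-mm sections (500 ROIs).
"""

import numpy as np

from stemresp import ROISpec, roi_coverage, simulate_oro_image, stain_mask

image = simulate_oro_image(1.0, droplet_radius_um=(40.0, 120.0),
                           um_per_px=20.0, size_px=(1500, 400), seed=8)
mask = stain_mask(image)
result = roi_coverage(mask, image.um_per_px, ROISpec(seed=0))

se = result.sd_pct / np.sqrt(result.n_rois)
print(f"ground-truth coverage : {image.true_coverage_pct:.3f} %")
print(f"ROI estimate          : {result.mean_coverage_pct:.3f} % "
      f"(SE {se:.3f}, n = {result.n_rois})")
print("per-section means     : "
      + " ".join(f"{m:.2f}" for m in result.per_section))
# The 500-ROI mean sits within a couple of standard errors of the realized
# pixel coverage; section means show the sampling noise of 50 ROIs each.
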