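"""Quantify per-cell ligand uptake from a rendered two-channel well image.

Renders one well (nuclei channel + punctate ligand channel with known
per-cell uptake), then runs the imaging chain: rolling-ball background
subtraction, gradient-based nuclei segmentation, nucleus-to-cell region
expansion and per-region intensity integration.  The recovered per-cell
intensities are compared with the rendered ground truth.
"""

import numpy as np

from mirtraffic import imagequant as iq
from mirtraffic.synthgen.screen import render_well_images

rng = np.random.default_rng(3)
true_uptake = rng.lognormal(np.log(1000), 0.5, 18)
field, gt_mask, _ = render_well_images(true_uptake, rng_seed=8)
print(f"rendered {len(true_uptake)} cells on a {field.shape} field")

mask = iq.segment_nuclei(field.channels["nuclei"])
print(f"segmented {mask.max()} nuclei (ground truth {gt_mask.max()})")

regions = iq.assign_cell_regions(mask, expansion_radius=10)
cells = iq.quantify_cells(field, regions, ball_radius=25, nuclei_mask=mask)

measured = np.array(sorted(c.ligand_intensity for c in cells))
expected = np.array(sorted(true_uptake))
rel_err = np.abs(measured - expected) / expected
print(f"median per-cell recovery error: {100 * np.median(rel_err):.1f}%")
print(f"well median uptake: measured {iq.well_median(cells):.0f}, true {np.median(true_uptake):.0f}")
print(
    "\nSmall losses come from punctum tails that fall outside the expanded"
    " cell region and 16-bit discretisation of faint punctum edges."
)
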