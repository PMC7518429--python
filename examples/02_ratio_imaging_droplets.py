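"""SRS ratio imaging and lipid-droplet spectroscopy.

Simulates a CH2/CH3 image pair with cells and bright droplets, computes
the Huang cell mask and the per-pixel CH2/CH3 lipid-to-protein ratio,
detects droplets, and quantifies their unsaturation (3022/2908) and
cholesteryl-ester (2974/2908) content from the hyperspectral stack.
"""

import numpy as np

from ramanmet import (
    detect_lipid_droplets,
    extract_region_spectrum,
    huang_threshold_mask,
    normalize_to_anchor,
    peak_ratio,
    ratio_image,
    synthetic,
)

ch2, ch3, stack, wns, truth = synthetic.simulate_srs_field(
    n_cells=4, droplets_per_cell=3, image_size=256, seed=0, hyperspectral=True
)
mask = huang_threshold_mask(ch3)
print(f"Huang threshold {mask.threshold_value:.4f} -> {mask.n_pixels} cell pixels")

rimg = ratio_image(ch2, ch3, mask)
droplets = detect_lipid_droplets(ch2, mask)

# cytoplasm ratio: droplet pixels are CH2-bright and would inflate the mean
droplet_px = np.zeros(ch2.shape, dtype=bool)
for reg in droplets.regions:
    droplet_px |= reg.pixels
labels = truth.extras["cell_labels"]
for k, planted in truth.extras["cell_ratio"].items():
    region = (labels == int(k)) & (mask.pixels != 0) & ~droplet_px
    print(f"cell {k}: planted cytoplasm CH2/CH3 {planted:.3f}, measured {rimg[region].mean():.3f}")
print(f"droplets: {len(droplets)} detected, {len(truth.droplet_centers)} planted")
ul, ce = [], []
for reg in droplets.regions:
    spec = normalize_to_anchor(extract_region_spectrum(stack, wns, reg.pixels))
    ul.append(peak_ratio(spec, 3022.0, 2908.0, half_window=0))
    ce.append(peak_ratio(spec, 2974.0, 2908.0, half_window=0))
print(
    f"droplet UL ratio (3022/2908): {np.mean(ul):.3f} (planted {truth.extras['ul_ratio']})\n"
    f"droplet CE ratio (2974/2908): {np.mean(ce):.3f} (planted {truth.extras['ce_ratio']})"
)
print(
    "-> per-cell ratios and droplet band ratios recover the planted values; "
    "higher UL/CE ratios flag droplets rich in unsaturated lipids and "
    "cholesteryl esters."
)
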