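"""Quantify patch (striosome) versus matrix fluorescence.

Builds a synthetic striatal field with bright elliptical patches (mean 200)
on a dimmer matrix (mean 100), pairs each patch ROI with a displaced matrix
ROI, and reports the per-pair intensity ratio and the fraction of the field
covered by patches.
"""

import numpy as np

from exmorph import (
    generate_compartment_image,
    pairs_from_labels,
    patch_area_fraction,
    patch_matrix_ratio,
)

image, patch_labels, matrix_labels, true_ratio = generate_compartment_image(
    shape=(512, 512), n_patches=5, patch_intensity=200, matrix_intensity=100,
    noise_sd=5.0, seed=11,
)
pairs = pairs_from_labels(patch_labels, matrix_labels)
result = patch_matrix_ratio(image, pairs)
area = patch_area_fraction(
    [patch_labels == k for k in range(1, 6)], np.ones(image.data.shape, dtype=bool)
)

print("per-pair patch/matrix ratios:", [f"{r:.3f}" for r in result.per_pair_ratio])
print(f"mean ratio: {result.mean_ratio:.3f}  (constructed truth {true_ratio:.1f})")
print(f"patch area fraction: {area:.4f}")
# A ratio > 1 means dopamine-axon fluorescence is enriched in patches
# relative to the surrounding matrix.
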