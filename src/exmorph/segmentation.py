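"""Probability-map post-processing: strict thresholding and small-object removal.

The two rules are applied literally: a voxel is foreground iff its probability
is *strictly greater* than the threshold (default 0.7), and connected
components with *fewer than* ``min_voxels`` voxels (default 256) are removed —
a component of exactly ``min_voxels`` voxels is kept.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import AxonMask, ProbabilityVolume

__all__ = [
    "ComponentReport",
    "threshold_volume",
    "remove_small_components",
    "segment",
    "connectivity_structure",
]

DEFAULT_THRESHOLD = 0.7
DEFAULT_MIN_VOXELS = 256
DEFAULT_CONNECTIVITY = 26


def connectivity_structure(connectivity: int) -> np.ndarray:
    """3×3×3 binary structuring element for 6-, 18- or 26-connectivity."""
    try:
        rank = {6: 1, 18: 2, 26: 3}[connectivity]
    except KeyError:
        raise ValueError(f"connectivity must be 6, 18 or 26, got {connectivity}") from None
    return ndimage.generate_binary_structure(3, rank)


@dataclass
class ComponentReport:
    """Bookkeeping of the size filter: what was there, what survived."""

    n_components_before: int
    n_components_after: int
    removed_voxels: int
    size_histogram: dict[int, int] = field(default_factory=dict)
    min_voxels: int = 1
    connectivity: int = DEFAULT_CONNECTIVITY


def threshold_volume(volume: ProbabilityVolume, threshold: float = DEFAULT_THRESHOLD) -> AxonMask:
    """Binarize a probability volume at ``p > threshold`` (strict inequality).

    A uniform volume at exactly the threshold value therefore yields an empty
    mask.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
    return AxonMask(
        volume.data > threshold,
        volume.spacing,
        threshold_used=float(threshold),
        min_component_voxels=1,
        name=volume.name,
    )


def remove_small_components(
    mask: AxonMask,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> tuple[AxonMask, ComponentReport]:
    """Drop connected components with fewer than ``min_voxels`` voxels.

    Components of size exactly ``min_voxels`` are kept. Components touching
    the volume border are treated like any other (no border correction).
    """
    if min_voxels < 1:
        raise ValueError(f"min_voxels must be >= 1, got {min_voxels}")
    structure = connectivity_structure(connectivity)
    labels, n_before = ndimage.label(mask.data, structure=structure)
    sizes = np.bincount(labels.ravel())[1:]  # drop background bin
    keep = sizes >= min_voxels
    removed_voxels = int(sizes[~keep].sum())
    surviving = np.zeros(n_before + 1, dtype=bool)
    surviving[1:] = keep
    out = AxonMask(
        surviving[labels],
        mask.spacing,
        threshold_used=mask.threshold_used,
        min_component_voxels=int(min_voxels),
        name=mask.name,
    )
    report = ComponentReport(
        n_components_before=int(n_before),
        n_components_after=int(keep.sum()),
        removed_voxels=removed_voxels,
        size_histogram=dict(sorted(Counter(int(s) for s in sizes).items())),
        min_voxels=int(min_voxels),
        connectivity=int(connectivity),
    )
    return out, report


def segment(
    volume: ProbabilityVolume,
    threshold: float = DEFAULT_THRESHOLD,
    min_voxels: int = DEFAULT_MIN_VOXELS,
    connectivity: int = DEFAULT_CONNECTIVITY,
) -> tuple[AxonMask, ComponentReport]:
    """Threshold then filter: the full probability-map → analysis-mask step."""
    mask = threshold_volume(volume, threshold)
    return remove_small_components(mask, min_voxels=min_voxels, connectivity=connectivity)
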