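"""Patch (striosome) versus matrix fluorescence quantification.

The striatum contains two neurochemical compartments: mu-opioid-receptor-rich
patches (striosomes) embedded in the surrounding matrix. Given a
max-projected image and pairs of regions of interest — one drawn inside a
patch, its partner moved just outside into matrix — this module computes the
per-pair ratio of mean patch intensity to mean matrix intensity, and the
fraction of a reference region covered by patches.

ROIs arrive as integer-labeled mask images: label ``k`` in the patch image
pairs with label ``k`` in the matrix image, making the computation
reproducible without the interactive tool the ROIs were drawn in.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import PlanarImage, ProbabilityVolume

__all__ = [
    "ROIPair",
    "CompartmentResult",
    "max_project",
    "pairs_from_labels",
    "patch_matrix_ratio",
    "patch_area_fraction",
]


@dataclass
class ROIPair:
    """A patch ROI and its displaced matrix partner; disjoint, both non-empty."""

    patch_mask: np.ndarray
    matrix_mask: np.ndarray
    pair_id: str = ""

    def __post_init__(self) -> None:
        self.patch_mask = np.asarray(self.patch_mask, dtype=bool)
        self.matrix_mask = np.asarray(self.matrix_mask, dtype=bool)
        if self.patch_mask.shape != self.matrix_mask.shape:
            raise ValueError("patch and matrix masks must share a shape")
        if not self.patch_mask.any() or not self.matrix_mask.any():
            raise ValueError(f"ROI pair {self.pair_id!r}: both masks must be non-empty")
        if (self.patch_mask & self.matrix_mask).any():
            raise ValueError(f"ROI pair {self.pair_id!r}: masks overlap")


@dataclass
class CompartmentResult:
    per_pair_ratio: list[float] = field(default_factory=list)
    mean_ratio: float = float("nan")
    patch_area_fraction: float = float("nan")
    n_pairs_excluded: int = 0


def max_project(volume: ProbabilityVolume) -> PlanarImage:
    """Per-pixel maximum along z."""
    if volume.shape[0] < 1:
        raise ValueError("volume has no z planes")
    return PlanarImage(volume.data.max(axis=0), name=volume.name)


def pairs_from_labels(patch_labels: np.ndarray, matrix_labels: np.ndarray) -> list[ROIPair]:
    """Build ROI pairs from two integer-labeled mask images.

    Label ``k > 0`` in the patch image pairs with label ``k`` in the matrix
    image; labels present in only one image are rejected.
    """
    patch_labels = np.asarray(patch_labels)
    matrix_labels = np.asarray(matrix_labels)
    labels_p = set(np.unique(patch_labels)) - {0}
    labels_m = set(np.unique(matrix_labels)) - {0}
    if labels_p != labels_m:
        raise ValueError(f"unpaired ROI labels: patch-only {sorted(labels_p - labels_m)}, matrix-only {sorted(labels_m - labels_p)}")
    return [
        ROIPair(patch_labels == k, matrix_labels == k, pair_id=str(int(k)))
        for k in sorted(labels_p)
    ]


def patch_matrix_ratio(image: PlanarImage, pairs: list[ROIPair]) -> CompartmentResult:
    """Per-pair ratio of mean patch intensity to mean matrix intensity.

    The ratio of *means* (not the mean of pixel ratios) is taken per ROI
    pair, then averaged across pairs. A pair whose matrix mean is zero is
    excluded with a warning and counted in ``n_pairs_excluded``.
    """
    if not pairs:
        raise ValueError("at least one ROI pair is required")
    ratios: list[float] = []
    excluded = 0
    for pair in pairs:
        if pair.patch_mask.shape != image.data.shape:
            raise ValueError(f"ROI pair {pair.pair_id!r} shape does not match image")
        patch_mean = float(image.data[pair.patch_mask].mean())
        matrix_mean = float(image.data[pair.matrix_mask].mean())
        if matrix_mean == 0:
            warnings.warn(f"ROI pair {pair.pair_id!r}: zero matrix mean, pair excluded")
            excluded += 1
            continue
        ratios.append(patch_mean / matrix_mean)
    mean_ratio = float(np.mean(ratios)) if ratios else float("nan")
    return CompartmentResult(
        per_pair_ratio=ratios, mean_ratio=mean_ratio, n_pairs_excluded=excluded
    )


def patch_area_fraction(patch_masks: list[np.ndarray], region_mask: np.ndarray) -> float:
    """Union area of the patch masks over the reference region area."""
    region_mask = np.asarray(region_mask, dtype=bool)
    if not region_mask.any():
        raise ValueError("region mask is empty")
    union = np.zeros_like(region_mask)
    for m in patch_masks:
        m = np.asarray(m, dtype=bool)
        if (m & ~region_mask).any():
            raise ValueError("patch pixels fall outside the reference region")
        union |= m
    return float(union.sum() / region_mask.sum())
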