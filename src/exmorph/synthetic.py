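"""Synthetic inputs with exact ground truth for every pipeline stage.

Three generators:

* **Tubular axon phantoms** — curvilinear centerlines drawn as persistent
  random walks, rasterized into a binary mask (voxels within a physical
  radius of the centerline) and dressed up as a CNN-like probability map
  (confident foreground at 0.95, background at 0.2 by default, optional
  Gaussian noise). Centerlines run until they exit the volume, emulating
  axons that traverse the imaged crop rather than terminating inside it.
  Ground truth (per-axon centerline, length, radius, voxel counts) is exact
  for the noiseless mask.
* **Pre/post expansion pairs** — a seeded multi-scale noise texture and its
  resampling under an exactly known similarity transform (uniform scale +
  rotation + translation), for validating the expansion-factor estimator.
* **Two-compartment striatal images** — bright elliptical patches on a
  dimmer matrix with paired displaced ROIs, for validating the patch/matrix
  ratio.

Determinism: all randomness flows from a master seed through per-axon
substreams, so adding axon n+1 never perturbs axons 1..n, and identical
spec + seed gives bit-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import binary_dilation, distance_transform_edt, gaussian_filter
from skimage.transform import SimilarityTransform, warp

from .io import AxonMask, PlanarImage, ProbabilityVolume

__all__ = [
    "PhantomSpec",
    "PhantomGroundTruth",
    "PhantomPlacementError",
    "generate_axon_phantom",
    "generate_expansion_pair",
    "generate_compartment_image",
    "PRESETS",
]

FOREGROUND_LEVEL = 0.95  # emulates a confident CNN output


class PhantomPlacementError(RuntimeError):
    """Raised when a non-overlapping axon cannot be placed within the retry cap."""


@dataclass
class PhantomSpec:
    """Parameters of a tubular axon phantom.

    shape/spacing mirror typical light-sheet inference crops (64³ voxels).
    ``radius`` is in voxels (scalar, or (lo, hi) range sampled per axon);
    ``tortuosity`` in [0, 1] scales the per-step direction perturbation
    (0 = straight); ``noise_sd`` is the sd of additive Gaussian noise on the
    probability map; ``background_level`` must stay below the fixed
    foreground level 0.95 so the default 0.7 threshold separates them.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    n_axons: int = 10
    radius: float | tuple[float, float] = 3.0
    tortuosity: float = 0.2
    noise_sd: float = 0.02
    background_level: float = 0.2
    seed: int = 0
    max_retries: int = 3000  # placement retries per axon
    min_length_um: float | None = None  # default: half the smallest volume extent

    def __post_init__(self) -> None:
        r_lo = self.radius[0] if isinstance(self.radius, tuple) else self.radius
        if r_lo < 1:
            raise ValueError("radius must be at least 1 voxel")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if not 0 <= self.background_level < FOREGROUND_LEVEL:
            raise ValueError(f"background_level must lie in [0, {FOREGROUND_LEVEL})")
        if not 0 <= self.tortuosity <= 1:
            raise ValueError("tortuosity must lie in [0, 1]")


@dataclass
class PhantomGroundTruth:
    """Exact per-axon and whole-volume truth for the noiseless mask."""

    centerlines_um: list[np.ndarray] = field(default_factory=list)  # (n_i, 3) (z,y,x)
    lengths_um: list[float] = field(default_factory=list)
    radii_um: list[float] = field(default_factory=list)
    radii_voxels: list[float] = field(default_factory=list)
    voxel_counts: list[int] = field(default_factory=list)
    foreground_voxels: int = 0
    volume_fraction: float = 0.0
    length_density: float = 0.0  # µm / µm³

    @property
    def total_length_um(self) -> float:
        return float(sum(self.lengths_um))

    @property
    def mean_radius_um(self) -> float:
        """Skeleton-length-weighted mean radius, matching how the pipeline pools."""
        if not self.radii_um:
            return 0.0
        w = np.asarray(self.lengths_um)
        return float(np.average(self.radii_um, weights=w) if w.sum() else np.mean(self.radii_um))


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _walk(
    rng: np.random.Generator,
    start: np.ndarray,
    direction: np.ndarray,
    step: float,
    tortuosity: float,
    lo: np.ndarray,
    hi: np.ndarray,
    max_steps: int,
) -> list[np.ndarray]:
    """Persistent random walk from start until it exits [lo, hi] (exclusive)."""
    pts = []
    p = start.copy()
    d = direction.copy()
    for _ in range(max_steps):
        p = p + d * step
        if np.any(p < lo) or np.any(p > hi):
            break
        pts.append(p)
        if tortuosity > 0:
            # von-Mises-style jitter: Gaussian kick then renormalize
            d = _unit(d + rng.normal(scale=0.25 * tortuosity, size=3))
    return pts


def _sample_centerline(
    rng: np.random.Generator, spec: PhantomSpec, radius_um: float
) -> np.ndarray:
    """One centerline traversing the volume interior, physical (z, y, x) µm.

    The walk is confined to an inner box one voxel plus one tube radius away
    from every face, so the rasterized tube (centerline dilated by its
    radius) lies fully inside the volume and the polyline length is exact
    ground truth for the rendered structure.
    """
    extent = np.asarray(spec.shape) * np.asarray(spec.spacing)
    margin = radius_um + float(max(spec.spacing))
    lo = margin * np.ones(3)
    hi = extent - margin
    if np.any(hi <= lo):
        raise ValueError("radius too large for the volume shape")
    start = rng.uniform(lo, hi)
    d = _unit(rng.normal(size=3))
    step = 0.5 * min(spec.spacing)
    max_steps = int(4 * extent.sum() / step)
    fwd = _walk(rng, start, d, step, spec.tortuosity, lo, hi, max_steps)
    bwd = _walk(rng, start, -d, step, spec.tortuosity, lo, hi, max_steps)
    pts = bwd[::-1] + [start] + fwd
    return np.asarray(pts)


def _polyline_length(points: np.ndarray) -> float:
    return float(np.linalg.norm(np.diff(points, axis=0), axis=1).sum())


def _resample_polyline(points: np.ndarray, step: float) -> np.ndarray:
    """Dense equal-arc-length resampling of a polyline."""
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    arclen = np.concatenate([[0.0], np.cumsum(seg)])
    total = arclen[-1]
    if total == 0:
        return points[:1]
    n = max(int(math.ceil(total / step)), 1)
    t = np.linspace(0.0, total, n + 1)
    out = np.empty((len(t), 3))
    for axis in range(3):
        out[:, axis] = np.interp(t, arclen, points[:, axis])
    return out


def _rasterize_tube(
    centerline: np.ndarray,
    radius_um: float,
    shape: tuple[int, int, int],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Voxels whose center lies within radius_um of the (densely sampled) centerline."""
    spacing_arr = np.asarray(spacing)
    samples = _resample_polyline(centerline, 0.25 * min(spacing))
    sq = np.full(shape, np.inf)
    # voxel center of index i is (i + 0.5) * spacing
    for p in samples:
        lo_idx = np.maximum(np.floor((p - radius_um) / spacing_arr - 0.5).astype(int), 0)
        hi_idx = np.minimum(np.ceil((p + radius_um) / spacing_arr - 0.5).astype(int) + 1, shape)
        if np.any(lo_idx >= hi_idx):
            continue
        grids = np.meshgrid(
            *[(np.arange(lo_idx[a], hi_idx[a]) + 0.5) * spacing_arr[a] - p[a] for a in range(3)],
            indexing="ij",
        )
        d2 = grids[0] ** 2 + grids[1] ** 2 + grids[2] ** 2
        window = sq[lo_idx[0]:hi_idx[0], lo_idx[1]:hi_idx[1], lo_idx[2]:hi_idx[2]]
        np.minimum(window, d2, out=window)
    return sq <= radius_um**2


def _inside_length(centerline: np.ndarray, shape, spacing) -> float:
    """Arc length of the centerline portion inside the volume box, µm."""
    extent = np.asarray(shape) * np.asarray(spacing)
    samples = _resample_polyline(centerline, 0.25 * min(spacing))
    seg = np.linalg.norm(np.diff(samples, axis=0), axis=1)
    mid = 0.5 * (samples[:-1] + samples[1:])
    inside = np.all((mid >= 0) & (mid <= extent), axis=1)
    return float(seg[inside].sum())


def generate_axon_phantom(
    spec: PhantomSpec,
) -> tuple[ProbabilityVolume, AxonMask, PhantomGroundTruth]:
    """Generate a tubular phantom: probability map, noiseless mask, ground truth.

    Axons are placed by rejection sampling so their voxel supports never
    overlap (keeping the ground-truth length density additive); after
    ``spec.max_retries`` failed placements a :class:`PhantomPlacementError`
    is raised rather than silently returning fewer axons.
    """
    streams = np.random.SeedSequence(spec.seed).spawn(spec.n_axons + 1)
    noise_rng = np.random.default_rng(streams[-1])
    spacing_arr = np.asarray(spec.spacing)
    max_radius_um = (
        spec.radius[1] if isinstance(spec.radius, tuple) else spec.radius
    ) * float(min(spec.spacing))
    if 2 * max_radius_um >= min(np.asarray(spec.shape) * spacing_arr):
        raise ValueError("radius too large for the volume shape")

    extent = np.asarray(spec.shape) * spacing_arr
    # axons traverse the imaged crop rather than terminating inside it
    min_length = spec.min_length_um if spec.min_length_um is not None else 0.5 * float(extent.min())
    occupied = np.zeros(spec.shape, dtype=bool)
    # physical distance from each voxel to the nearest occupied voxel
    clearance = np.full(spec.shape, np.inf)
    truth = PhantomGroundTruth()
    for i in range(spec.n_axons):
        rng = np.random.default_rng(streams[i])
        placed = False
        for _ in range(spec.max_retries):
            if isinstance(spec.radius, tuple):
                radius_vox = float(rng.uniform(spec.radius[0], spec.radius[1]))
            else:
                radius_vox = float(spec.radius)
            radius_um = radius_vox * float(min(spec.spacing))
            centerline = _sample_centerline(rng, spec, radius_um)
            if len(centerline) < 2 or _polyline_length(centerline) < min_length:
                continue
            # require a >1-voxel gap to earlier axons so thinning never fuses
            # two tubes into one armature (keeps ground truth additive):
            # clearance along the centerline must exceed radius + one voxel
            samples = _resample_polyline(centerline, 0.5 * min(spec.spacing))
            idx = np.clip(
                np.floor(samples / spacing_arr).astype(int), 0, np.asarray(spec.shape) - 1
            )
            gap = float(max(spec.spacing))
            if np.any(clearance[idx[:, 0], idx[:, 1], idx[:, 2]] <= radius_um + gap):
                continue
            tube = _rasterize_tube(centerline, radius_um, spec.shape, spec.spacing)
            if not tube.any():
                continue
            occupied |= tube
            clearance = distance_transform_edt(~occupied, sampling=spec.spacing)
            truth.centerlines_um.append(centerline)
            truth.lengths_um.append(_inside_length(centerline, spec.shape, spec.spacing))
            truth.radii_um.append(radius_um)
            truth.radii_voxels.append(radius_vox)
            truth.voxel_counts.append(int(tube.sum()))
            placed = True
            break
        if not placed:
            raise PhantomPlacementError(
                f"could not place axon {i + 1}/{spec.n_axons} without overlap "
                f"after {spec.max_retries} retries"
            )

    truth.foreground_voxels = int(occupied.sum())
    truth.volume_fraction = truth.foreground_voxels / occupied.size
    physical_volume = float(np.prod(spec.shape) * np.prod(spec.spacing))
    truth.length_density = truth.total_length_um / physical_volume

    prob = np.where(occupied, FOREGROUND_LEVEL, spec.background_level)
    if spec.noise_sd > 0:
        prob = prob + noise_rng.normal(scale=spec.noise_sd, size=spec.shape)
    prob = np.clip(prob, 0.0, 1.0)
    name = f"phantom-seed{spec.seed}"
    volume = ProbabilityVolume(prob, spec.spacing, name=name)
    mask = AxonMask(occupied, spec.spacing, threshold_used=float("nan"), name=name)
    return volume, mask, truth


# named parameter sets for batch generation; "raptor-like" mimics the sparser,
# thinner innervation phenotype, "wild-type-like" the dense control condition
PRESETS: dict[str, dict] = {
    "default": {},
    "sparse": {"n_axons": 5, "radius": (2.0, 4.0)},
    "dense": {"n_axons": 25, "radius": (2.0, 5.0)},
    "raptor-like": {"n_axons": 8, "radius": (2.0, 3.0)},
    "wild-type-like": {"n_axons": 18, "radius": (2.5, 4.5)},
}


def _texture(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Multi-scale filtered noise plus Gaussian blobs: SIFT-friendly structure."""
    img = np.zeros(shape)
    for sigma, weight in ((1.0, 0.5), (2.0, 1.0), (4.0, 1.5), (8.0, 2.0)):
        img += weight * gaussian_filter(rng.normal(size=shape), sigma)
    # sprinkle bright blobs of varied size
    n_blobs = max(10, int(np.prod(shape) / 2000))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for _ in range(n_blobs):
        cy, cx = rng.uniform(0, shape[0]), rng.uniform(0, shape[1])
        s = rng.uniform(1.5, 6.0)
        amp = rng.uniform(1.0, 3.0)
        img += amp * np.exp(-((yy - cy) ** 2 + (xx - cx) ** 2) / (2 * s**2))
    img -= img.min()
    img /= img.max()
    return img


def generate_expansion_pair(
    texture_seed: int = 0,
    scale: float = 4.25,
    rotation_deg: float = 0.0,
    translation: tuple[float, float] = (0.0, 0.0),
    noise_sd: float = 0.0,
    pre_shape: tuple[int, int] = (160, 160),
) -> tuple[PlanarImage, PlanarImage, SimilarityTransform]:
    """Create a pre/post-expansion image pair under a known similarity transform.

    The default scale magnitude (4.25) matches typical protein-retention
    expansion-microscopy factors. Returns (pre, post, true_transform) where
    the transform maps pre-image (x, y) pixel coordinates onto post-image
    coordinates; its ``scale`` attribute is the true expansion factor.
    """
    if scale <= 0:
        raise ValueError("scale must be positive")
    rng = np.random.default_rng(texture_seed)
    pre = _texture(rng, pre_shape)
    post_shape = (int(round(pre_shape[0] * scale)), int(round(pre_shape[1] * scale)))

    # map the pre center onto the post center, then rotate/scale about it
    c_pre = np.array([pre_shape[1] / 2, pre_shape[0] / 2])  # (x, y)
    c_post = np.array([post_shape[1] / 2, post_shape[0] / 2])
    theta = math.radians(rotation_deg)
    center_in = SimilarityTransform(translation=-c_pre)
    rotscale = SimilarityTransform(scale=scale, rotation=theta)
    center_out = SimilarityTransform(
        translation=c_post + np.array([translation[1], translation[0]])
    )
    tform = SimilarityTransform(matrix=center_out.params @ rotscale.params @ center_in.params)

    post = warp(pre, tform.inverse, output_shape=post_shape, order=3, mode="constant", cval=0.0)
    if noise_sd > 0:
        post = post + rng.normal(scale=noise_sd, size=post.shape)
        pre = pre + rng.normal(scale=noise_sd, size=pre.shape)
    return (
        PlanarImage(pre, name=f"pre-seed{texture_seed}"),
        PlanarImage(post, name=f"post-seed{texture_seed}"),
        tform,
    )


def generate_compartment_image(
    shape: tuple[int, int] = (512, 512),
    n_patches: int = 5,
    patch_intensity: float = 200.0,
    matrix_intensity: float = 100.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    max_retries: int = 500,
) -> tuple[PlanarImage, np.ndarray, np.ndarray, float]:
    """Two-compartment striatal image with paired patch/matrix ROI labels.

    Bright elliptical patches (label k in the patch image) sit on a dimmer
    matrix; each patch ROI has a displaced twin (same label k in the matrix
    image) placed entirely outside every patch. Returns
    (image, patch_labels, matrix_labels, true_ratio) where
    ``true_ratio = patch_intensity / matrix_intensity``.
    """
    if patch_intensity < 0 or matrix_intensity < 0:
        raise ValueError("intensities must be non-negative")
    if matrix_intensity == 0:
        raise ValueError("matrix intensity must be positive for a defined ratio")
    rng = np.random.default_rng(seed)
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    patch_labels = np.zeros(shape, dtype=np.int32)
    matrix_labels = np.zeros(shape, dtype=np.int32)
    patch_union = np.zeros(shape, dtype=bool)
    ellipses: list[tuple[float, float, float, float, float]] = []

    def ellipse_mask(cy, cx, ry, rx, theta):
        dy, dx = yy - cy, xx - cx
        u = dx * math.cos(theta) + dy * math.sin(theta)
        v = -dx * math.sin(theta) + dy * math.cos(theta)
        return (u / rx) ** 2 + (v / ry) ** 2 <= 1.0

    for k in range(1, n_patches + 1):
        for _ in range(max_retries):
            ry, rx = rng.uniform(0.04, 0.09, size=2) * min(shape)
            cy = rng.uniform(ry, shape[0] - ry)
            cx = rng.uniform(rx, shape[1] - rx)
            theta = rng.uniform(0, math.pi)
            m = ellipse_mask(cy, cx, ry, rx, theta)
            if not (m & patch_union).any():
                patch_union |= m
                patch_labels[m] = k
                ellipses.append((cy, cx, ry, rx, theta))
                break
        else:
            raise RuntimeError(f"could not place patch {k}/{n_patches} without overlap")

    # dilate the union a little so matrix ROIs keep clear of patch borders
    pad = 3
    forbidden = binary_dilation(patch_union, iterations=pad)
    for k, (cy, cx, ry, rx, theta) in enumerate(ellipses, start=1):
        for _ in range(max_retries):
            ny = rng.uniform(ry, shape[0] - ry)
            nx = rng.uniform(rx, shape[1] - rx)
            m = ellipse_mask(ny, nx, ry, rx, theta)
            if not (m & forbidden).any():
                matrix_labels[m] = k
                forbidden |= m  # keep later matrix ROIs from overwriting this one
                break
        else:
            raise RuntimeError(f"could not place matrix ROI for patch {k} outside patches")

    img = np.where(patch_union, patch_intensity, matrix_intensity).astype(np.float64)
    if noise_sd > 0:
        img = img + rng.normal(scale=noise_sd, size=shape)
    true_ratio = patch_intensity / matrix_intensity
    return PlanarImage(img, name=f"compartments-seed{seed}"), patch_labels, matrix_labels, true_ratio
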