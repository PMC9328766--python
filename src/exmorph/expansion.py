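"""Linear expansion-factor estimation from a pre-/post-expansion image pair.

Scale-invariant (SIFT) keypoints are detected on both images, descriptors are
matched with a Lowe ratio test, and a similarity transform (rotation +
translation + uniform scale) is fitted robustly with RANSAC. The expansion
factor is the uniform scale of the fitted transform, extracted as √det of its
2×2 linear block, which equals the scale exactly for a similarity and is
robust to tiny numerical shear. A fit with a negative determinant (a
reflection) or too few keypoints/matches/inliers is reported as an estimation
failure carrying full diagnostics — never a silent number.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import SimilarityTransform

from .io import PlanarImage

__all__ = [
    "MatchingParams",
    "ExpansionEstimate",
    "ExpansionEstimationError",
    "estimate_expansion",
    "summarize_factors",
]


@dataclass
class MatchingParams:
    """Knobs of the keypoint-matching / robust-fitting stage.

    ratio_threshold:
        Lowe ratio-test threshold on descriptor distances (default 0.75).
    residual_threshold:
        RANSAC inlier reprojection threshold in pixels (default 3).
    min_inliers:
        Minimum consensus-set size for a trusted estimate (default 10).
    min_keypoints:
        Minimum keypoints per image before matching is attempted.
    max_trials:
        RANSAC iteration budget.
    seed:
        Seed of the RANSAC sampler; fixed for determinism (default 0).
    """

    ratio_threshold: float = 0.75
    residual_threshold: float = 3.0
    min_inliers: int = 10
    min_keypoints: int = 10
    max_trials: int = 2000
    seed: int = 0


@dataclass
class ExpansionEstimate:
    """Recovered similarity transform plus matching diagnostics."""

    scale: float
    rotation_deg: float
    translation: tuple[float, float]  # (dy, dx), pixels
    n_keypoints_pre: int
    n_keypoints_post: int
    n_matches: int
    n_inliers: int
    rms_inlier_residual: float  # pixels


class ExpansionEstimationError(RuntimeError):
    """Raised when no trustworthy transform can be estimated.

    Carries the same diagnostic counts as a successful estimate so failures
    are auditable.
    """

    def __init__(self, reason: str, **diagnostics: float):
        self.reason = reason
        self.diagnostics = diagnostics
        detail = ", ".join(f"{k}={v}" for k, v in diagnostics.items())
        super().__init__(f"expansion estimation failed: {reason} ({detail})")


def _detect(image: PlanarImage) -> tuple[np.ndarray, np.ndarray]:
    data = image.data
    rng_span = data.max() - data.min()
    if rng_span == 0:
        return np.empty((0, 2)), np.empty((0, 128))
    normed = (data - data.min()) / rng_span
    sift = SIFT()
    try:
        sift.detect_and_extract(normed)
    except RuntimeError:  # no features found
        return np.empty((0, 2)), np.empty((0, 128))
    return sift.keypoints, sift.descriptors


def estimate_expansion(
    pre: PlanarImage,
    post: PlanarImage,
    params: MatchingParams | None = None,
) -> ExpansionEstimate:
    """Estimate the similarity transform mapping the pre- onto the post-expansion image.

    Returns an :class:`ExpansionEstimate` whose ``scale`` is the linear
    expansion factor. Raises :class:`ExpansionEstimationError` on blank
    images, too few keypoints/matches, a degenerate fit, or fewer inliers
    than ``params.min_inliers``.
    """
    params = params or MatchingParams()
    kp_pre, desc_pre = _detect(pre)
    kp_post, desc_post = _detect(post)
    diag = {"n_keypoints_pre": len(kp_pre), "n_keypoints_post": len(kp_post)}
    if min(len(kp_pre), len(kp_post)) < params.min_keypoints:
        raise ExpansionEstimationError("too few keypoints", **diag)

    matches = match_descriptors(
        desc_pre, desc_post, max_ratio=params.ratio_threshold, cross_check=True
    )
    diag["n_matches"] = len(matches)
    if len(matches) < max(params.min_inliers, 3):
        raise ExpansionEstimationError("too few descriptor matches", **diag)

    # skimage transforms act on (x, y); keypoints come as (row, col)
    src = kp_pre[matches[:, 0]][:, ::-1].astype(np.float64)
    dst = kp_post[matches[:, 1]][:, ::-1].astype(np.float64)
    model, inliers = ransac(
        (src, dst),
        SimilarityTransform,
        min_samples=2,
        residual_threshold=params.residual_threshold,
        max_trials=params.max_trials,
        rng=params.seed,
    )
    if model is None or inliers is None:
        raise ExpansionEstimationError("robust fit did not converge", **diag)
    n_inliers = int(inliers.sum())
    diag["n_inliers"] = n_inliers
    if n_inliers < params.min_inliers:
        raise ExpansionEstimationError("too few inliers", **diag)

    # refit on the consensus set for the final parameters
    final = SimilarityTransform.from_estimate(src[inliers], dst[inliers])
    if not final:
        raise ExpansionEstimationError("final fit degenerate", **diag)
    linear = final.params[:2, :2]
    det = float(np.linalg.det(linear))
    if det <= 0:
        raise ExpansionEstimationError("fit is a reflection (negative determinant)", **diag)
    scale = math.sqrt(det)
    rotation_deg = math.degrees(math.atan2(linear[1, 0], linear[0, 0]))
    residuals = final.residuals(src[inliers], dst[inliers])
    tx, ty = (float(t) for t in final.params[:2, 2])
    return ExpansionEstimate(
        scale=scale,
        rotation_deg=rotation_deg,
        translation=(ty, tx),
        n_keypoints_pre=len(kp_pre),
        n_keypoints_post=len(kp_post),
        n_matches=len(matches),
        n_inliers=n_inliers,
        rms_inlier_residual=float(np.sqrt(np.mean(residuals**2))),
    )


def summarize_factors(estimates: list[ExpansionEstimate]) -> tuple[float, float, int]:
    """Mean ± SEM of the recovered scales across image pairs.

    Returns ``(mean, sem, n)``. With a single estimate the SEM is undefined
    and reported as 0.0 (n in the return value flags this case).
    """
    if not estimates:
        raise ValueError("no estimates to summarize")
    scales = np.array([e.scale for e in estimates], dtype=np.float64)
    n = len(scales)
    sem = float(scales.std(ddof=1) / math.sqrt(n)) if n > 1 else 0.0
    return float(scales.mean()), sem, n
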