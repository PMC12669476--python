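"""Cross-stain registration and training-pair curation.

Phase images of a tissue section captured before and after chemical staining
are similar enough for feature-based registration: SIFT keypoints are
matched (ratio test) and a perspective transform estimated with RANSAC.
Registration direction is unstained -> stained, since the stained amplitude
is the grid the virtual-staining target lives on. Registered fields are
tiled into 256x256 patches and filtered by the mutual information of the two
phase patches — a cutoff of 0.4 bits rejects patches dominated by
background or reconstruction artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.feature import SIFT, match_descriptors
from skimage.measure import ransac
from skimage.transform import AffineTransform, ProjectiveTransform, SimilarityTransform, warp

__all__ = [
    "PatchPair",
    "RegistrationError",
    "register_perspective",
    "mutual_information",
    "curate_pairs",
    "chromatic_align",
    "white_balance",
    "histogram_match_color",
    "corner_error",
]

DEFAULT_MI_CUTOFF = 0.4  # bits, 64-bin joint histogram of min–max-scaled patches
DEFAULT_MI_BINS = 64


class RegistrationError(RuntimeError):
    pass


@dataclass
class PatchPair:
    """A registered (unstained-phase, stained-RGB) training patch."""

    phase_patch: np.ndarray  # (256, 256) radians
    rgb_patch: np.ndarray  # (256, 256, 3) in [0, 1]
    mi_score: float
    accepted: bool
    coords: tuple[int, int]  # top-left (row, col) in the source field

    def __post_init__(self) -> None:
        if self.phase_patch.shape != self.rgb_patch.shape[:2]:
            raise ValueError("phase and rgb patches must share a pixel grid")


def _to_u8(img: np.ndarray) -> np.ndarray:
    """Contrast-stretch to uint8 for the keypoint detector (1st–99th pct)."""
    img = np.asarray(img, float)
    lo, hi = np.percentile(img, [1, 99])
    if hi <= lo:
        return np.zeros(img.shape, np.uint8)
    return (np.clip((img - lo) / (hi - lo), 0, 1) * 255).astype(np.uint8)


def _sift_matches(moving: np.ndarray, fixed: np.ndarray, max_ratio: float = 0.75):
    det_m, det_f = SIFT(), SIFT()
    try:
        det_m.detect_and_extract(_to_u8(moving))
        det_f.detect_and_extract(_to_u8(fixed))
    except RuntimeError as exc:  # featureless input
        raise RegistrationError(str(exc)) from exc
    matches = match_descriptors(det_m.descriptors, det_f.descriptors,
                                max_ratio=max_ratio, cross_check=True)
    src = det_m.keypoints[matches[:, 0]][:, ::-1]  # (x, y)
    dst = det_f.keypoints[matches[:, 1]][:, ::-1]
    return src, dst


def register_perspective(
    moving: np.ndarray,
    fixed: np.ndarray,
    max_ratio: float = 0.75,
    residual_threshold: float = 3.0,
    max_trials: int = 2000,
    min_inliers: int = 8,
    seed: int = 0,
):
    """Estimate the homography warping ``moving`` onto ``fixed``.

    Returns ``(H, warped, n_inliers)`` where ``H`` maps moving (x, y, 1)
    coordinates to fixed coordinates. Raises :class:`RegistrationError` with
    diagnostics when fewer than ``min_inliers`` consistent matches survive.
    """
    src, dst = _sift_matches(moving, fixed, max_ratio)
    if len(src) < max(4, min_inliers):
        raise RegistrationError(
            f"only {len(src)} SIFT matches; need at least {max(4, min_inliers)}")
    model, inliers = ransac(
        (src, dst), ProjectiveTransform, min_samples=4,
        residual_threshold=residual_threshold, max_trials=max_trials,
        rng=seed,
    )
    n_in = int(inliers.sum()) if inliers is not None else 0
    if model is None or n_in < min_inliers:
        raise RegistrationError(
            f"RANSAC found {n_in} inliers of {len(src)} matches "
            f"(threshold {residual_threshold} px)")
    warped = warp(np.asarray(moving, float), model.inverse, order=1, preserve_range=True)
    return model.params, warped, n_in


def corner_error(H_est: np.ndarray, H_true: np.ndarray, shape: tuple[int, int]) -> float:
    """Mean displacement of the image corners under H_est vs H_true (px)."""
    h, w = shape
    pts = np.array([[0, 0, 1], [w - 1, 0, 1], [0, h - 1, 1], [w - 1, h - 1, 1]], float).T

    def apply(H):
        q = H @ pts
        return q[:2] / q[2]

    return float(np.linalg.norm(apply(H_est) - apply(H_true), axis=0).mean())


def mutual_information(a: np.ndarray, b: np.ndarray, n_bins: int = DEFAULT_MI_BINS) -> float:
    """Mutual information in bits from the joint histogram of two images.

    Each image is min–max scaled before binning; a constant image carries no
    information and returns 0 (with a warning flag via warnings).
    """
    a, b = np.asarray(a, float).ravel(), np.asarray(b, float).ravel()
    if a.shape != b.shape:
        raise ValueError("shapes must match")

    def scaled(x):
        lo, hi = x.min(), x.max()
        return None if hi == lo else (x - lo) / (hi - lo)

    sa, sb = scaled(a), scaled(b)
    if sa is None or sb is None:
        warnings.warn("constant image: MI = 0", stacklevel=2)
        return 0.0
    joint, _, _ = np.histogram2d(sa, sb, bins=n_bins, range=[[0, 1], [0, 1]])
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log2(p[nz] / (px @ py)[nz])))


def curate_pairs(
    phase_unstained: np.ndarray,
    phase_stained: np.ndarray,
    rgb_stained: np.ndarray,
    patch_size: int = 256,
    mi_cutoff: float = DEFAULT_MI_CUTOFF,
    n_bins: int = DEFAULT_MI_BINS,
) -> list[PatchPair]:
    """Tile registered fields into patches and accept those with MI >= cutoff.

    MI is computed between the unstained and stained *phase* patches (the two
    modalities that were registered); the stained RGB patch rides along as
    the training target. Background-only patches have near-zero MI and fall
    below any reasonable cutoff.
    """
    if mi_cutoff == DEFAULT_MI_CUTOFF and n_bins != DEFAULT_MI_BINS:
        warnings.warn(
            "MI cutoff 0.4 is calibrated for the 64-bin estimator; "
            "reconsider the cutoff for a different binning", stacklevel=2)
    if phase_unstained.shape != phase_stained.shape:
        raise ValueError("registered fields must share a pixel grid")
    pairs = []
    H, W = phase_unstained.shape
    for i in range(0, H - patch_size + 1, patch_size):
        for j in range(0, W - patch_size + 1, patch_size):
            sl = (slice(i, i + patch_size), slice(j, j + patch_size))
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                mi = mutual_information(phase_unstained[sl], phase_stained[sl], n_bins)
            pairs.append(PatchPair(
                phase_patch=phase_unstained[sl].copy(),
                rgb_patch=np.asarray(rgb_stained, float)[sl].copy(),
                mi_score=mi,
                accepted=bool(mi >= mi_cutoff),
                coords=(i, j),
            ))
    return pairs


def chromatic_align(
    r: np.ndarray,
    g: np.ndarray,
    b: np.ndarray,
    mode: str = "affine",
    residual_threshold: float = 3.0,
    seed: int = 0,
):
    """Warp the red and blue channels onto the green by SIFT-matched affines.

    Lateral chromatic aberration shifts and scales the channels slightly
    against each other; ``mode="similarity"`` restricts the fit to
    scale/rotation/translation. Returns ``(rgb_aligned, transforms)`` where
    transforms maps channel name to the 3x3 matrix used (identity with a
    warning when matching fails).
    """
    tf_cls = {"affine": AffineTransform, "similarity": SimilarityTransform}[mode]
    aligned = {"g": np.asarray(g, float)}
    transforms = {"g": np.eye(3)}
    for name, chan in (("r", r), ("b", b)):
        chan = np.asarray(chan, float)
        try:
            src, dst = _sift_matches(chan, aligned["g"])
            if len(src) < 8:
                raise RegistrationError(f"{len(src)} matches")
            model, inliers = ransac((src, dst), tf_cls, min_samples=3,
                                    residual_threshold=residual_threshold,
                                    max_trials=1000, rng=seed)
            if model is None or inliers.sum() < 6:
                raise RegistrationError("too few RANSAC inliers")
            aligned[name] = warp(chan, model.inverse, order=1, preserve_range=True)
            transforms[name] = model.params
        except RegistrationError as exc:
            warnings.warn(f"chromatic alignment of {name!r} failed ({exc}); "
                          "keeping identity", stacklevel=2)
            aligned[name] = chan
            transforms[name] = np.eye(3)
    rgb = np.stack([aligned["r"], aligned["g"], aligned["b"]], axis=-1)
    return rgb, transforms


def white_balance(rgb: np.ndarray, background_roi: tuple[slice, slice]) -> np.ndarray:
    """Divide each channel by its mean over a background RoI; clip to [0, 1]."""
    rgb = np.asarray(rgb, float)
    roi = rgb[background_roi]
    means = roi.reshape(-1, rgb.shape[-1]).mean(axis=0)
    if np.any(means <= 0):
        raise ValueError("background RoI has a zero-mean channel")
    return np.clip(rgb / means, 0.0, 1.0)


def histogram_match_color(src_rgb: np.ndarray, ref_rgb: np.ndarray,
                          n_bins: int = 256) -> np.ndarray:
    """Per-channel monotone histogram remap of src onto ref."""
    from .recon import histogram_match_gray

    src = np.asarray(src_rgb, float)
    ref = np.asarray(ref_rgb, float)
    out = np.empty_like(src)
    for c in range(src.shape[-1]):
        out[..., c] = histogram_match_gray(src[..., c], ref[..., c], n_bins)
    return out
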