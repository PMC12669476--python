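"""Shared geometric warps: homographies and Brown–Conrady lens distortion.

One resampling convention is used everywhere: bilinear interpolation with
pixel centres at integer coordinates, origin at the top-left pixel,
coordinates ordered (x, y) = (col, row) inside transform matrices.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.transform import ProjectiveTransform, warp

__all__ = [
    "warp_homography",
    "brown_conrady_forward",
    "brown_conrady_inverse",
    "distortion_grid",
]


def warp_homography(img: np.ndarray, H: np.ndarray, order: int = 1, cval: float = 0.0) -> np.ndarray:
    """Apply a 3x3 homography (maps source (x, y, 1) -> destination)."""
    H = np.asarray(H, dtype=np.float64)
    if H.shape != (3, 3) or abs(np.linalg.det(H)) < 1e-12:
        raise ValueError("homography must be an invertible 3x3 matrix")
    tf = ProjectiveTransform(matrix=H)
    return warp(img, tf.inverse, order=order, cval=cval, preserve_range=True).astype(img.dtype, copy=False)


def brown_conrady_forward(
    xy: np.ndarray,
    k1: float = 0.0,
    k2: float = 0.0,
    p1: float = 0.0,
    p2: float = 0.0,
    center: tuple[float, float] = (0.0, 0.0),
    focal: float = 1.0,
) -> np.ndarray:
    """Map undistorted pixel coords (n, 2) to distorted coords.

    Radial terms k1, k2 and tangential terms p1, p2 act on coordinates
    normalised by ``focal`` around ``center`` (both in pixels).
    """
    x = (xy[..., 0] - center[0]) / focal
    y = (xy[..., 1] - center[1]) / focal
    r2 = x * x + y * y
    rad = 1.0 + k1 * r2 + k2 * r2 * r2
    xd = x * rad + 2 * p1 * x * y + p2 * (r2 + 2 * x * x)
    yd = y * rad + p1 * (r2 + 2 * y * y) + 2 * p2 * x * y
    out = np.empty_like(xy, dtype=np.float64)
    out[..., 0] = xd * focal + center[0]
    out[..., 1] = yd * focal + center[1]
    return out


def brown_conrady_inverse(
    xy_dist: np.ndarray, n_iter: int = 20, **params
) -> np.ndarray:
    """Invert the distortion by fixed-point iteration (sub-0.01 px for mild lenses)."""
    xy = np.array(xy_dist, dtype=np.float64)
    for _ in range(n_iter):
        delta = brown_conrady_forward(xy, **params) - xy
        xy = xy_dist - delta
    return xy


def distortion_grid(shape: tuple[int, int], inverse: bool, **params) -> np.ndarray:
    """Sampling coordinates (2, H, W) in (row, col) order for map_coordinates.

    ``inverse=False`` gives the grid that *renders* a distorted image from a
    flat one; ``inverse=True`` gives the grid that corrects a distorted image.
    """
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w].astype(np.float64)
    xy = np.stack([xx.ravel(), yy.ravel()], axis=-1)
    src = brown_conrady_inverse(xy, **params) if not inverse else brown_conrady_forward(xy, **params)
    return np.stack([src[:, 1].reshape(h, w), src[:, 0].reshape(h, w)])


def resample(img: np.ndarray, coords: np.ndarray, order: int = 1) -> np.ndarray:
    return ndi.map_coordinates(img, coords, order=order, mode="nearest")
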