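"""Image-quality evaluation: similarity metrics, colour difference, and
decorrelation-analysis resolution estimation.

The similarity metrics (SSIM, RMSE, PSNR, PCC) are computed *globally* per
patch from their textbook definitions::

    SSIM = (2 mu_x mu_y + C1)(2 sigma_xy + C2) /
           ((mu_x^2 + mu_y^2 + C1)(sigma_x^2 + sigma_y^2 + C2))
    RMSE = sqrt(mean((x - y)^2));  PSNR = 10 log10(R^2 / RMSE^2)
    PCC  = sigma_xy / (sigma_x sigma_y)

with C1 = (0.01 R)^2 and C2 = (0.03 R)^2 for dynamic range R. A sliding
window SSIM is provided but non-default, since evaluation is per 256x256
patch anyway.

Spatial resolution is estimated with image decorrelation analysis: the
cross-correlation of the Fourier transform with its phase-only (amplitude
normalised) copy restricted to disks of growing radius peaks near the
highest frequency that carries signal above the noise; repeating over a
series of Gaussian high-pass pre-filters sharpens the peak, and the cutoff
is the highest frequency at which any curve has a local maximum, in units of
the grid Nyquist.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from scipy import stats
from skimage.color import rgb2lab

__all__ = [
    "to_gray",
    "ssim",
    "ssim_windowed",
    "rmse",
    "psnr",
    "pcc",
    "delta_e",
    "lab_histograms",
    "decorrelation_cutoff",
    "ResolutionEstimate",
    "cutoff_heatmap",
    "welch_t",
    "patch_metrics",
]

GRAY_WEIGHTS = np.array([0.299, 0.587, 0.114])


def to_gray(rgb: np.ndarray) -> np.ndarray:
    """Luma conversion Y = 0.299 R + 0.587 G + 0.114 B."""
    rgb = np.asarray(rgb, float)
    if rgb.ndim == 2:
        return rgb.copy()
    return rgb[..., :3] @ GRAY_WEIGHTS


def _moments(x, y):
    mx, my = x.mean(), y.mean()
    sx, sy = x.std(), y.std()
    sxy = ((x - mx) * (y - my)).mean()
    return mx, my, sx, sy, sxy


def ssim(x: np.ndarray, y: np.ndarray, R: float = 1.0) -> float:
    """Global structural similarity of two equally shaped patches."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if x.shape != y.shape:
        raise ValueError("shapes must match")
    c1, c2 = (0.01 * R) ** 2, (0.03 * R) ** 2
    mx, my, sx, sy, sxy = _moments(x, y)
    return float(
        (2 * mx * my + c1) * (2 * sxy + c2)
        / ((mx**2 + my**2 + c1) * (sx**2 + sy**2 + c2))
    )


def ssim_windowed(x: np.ndarray, y: np.ndarray, R: float = 1.0, win: int = 7) -> float:
    """Mean of local SSIM over a uniform sliding window (non-default variant)."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    c1, c2 = (0.01 * R) ** 2, (0.03 * R) ** 2
    u = lambda a: ndi.uniform_filter(a, win)
    mx, my = u(x), u(y)
    sxx, syy, sxy = u(x * x) - mx**2, u(y * y) - my**2, u(x * y) - mx * my
    s = ((2 * mx * my + c1) * (2 * sxy + c2)
         / ((mx**2 + my**2 + c1) * (sxx + syy + c2)))
    return float(s.mean())


def rmse(x: np.ndarray, y: np.ndarray) -> float:
    x, y = np.asarray(x, float), np.asarray(y, float)
    return float(np.sqrt(np.mean((x - y) ** 2)))


def psnr(x: np.ndarray, y: np.ndarray, R: float = 1.0) -> float:
    r = rmse(x, y)
    if r == 0:
        return float("inf")
    return float(10 * np.log10(R**2 / r**2))


def pcc(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation; raises on zero-variance input."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    _, _, sx, sy, sxy = _moments(x, y)
    if sx == 0 or sy == 0:
        raise ValueError("PCC undefined for zero-variance input")
    return float(sxy / (sx * sy))


def delta_e(rgb_a: np.ndarray, rgb_b: np.ndarray, mask: np.ndarray | None = None) -> float:
    """Mean CIE76 colour difference: Euclidean distance in CIE Lab* (sRGB/D65)."""
    lab_a = rgb2lab(np.clip(np.asarray(rgb_a, float), 0, 1))
    lab_b = rgb2lab(np.clip(np.asarray(rgb_b, float), 0, 1))
    de = np.sqrt(((lab_a - lab_b) ** 2).sum(axis=-1))
    if mask is not None:
        de = de[mask]
    return float(de.mean())


def lab_histograms(rgb: np.ndarray, bins: int = 100):
    """Histograms of L* in [0, 100] and a*, b* in [-128, 127]."""
    lab = rgb2lab(np.clip(np.asarray(rgb, float), 0, 1))
    out = {}
    for i, (name, rng) in enumerate([("L", (0, 100)), ("a", (-128, 127)), ("b", (-128, 127))]):
        hist, edges = np.histogram(lab[..., i].ravel(), bins=bins, range=rng)
        out[name] = (hist, edges)
    return out


class ResolutionEstimate:
    """Result of decorrelation analysis.

    Attributes
    ----------
    cutoff : highest-frequency local maximum over all curves, as a fraction
        of the grid Nyquist; ``nan`` when no maximum is found (flat image).
    radii : mask radii (fractions of Nyquist) the curves are sampled at.
    curves : (n_highpass + 1, n_radii) decorrelation functions, first row
        unfiltered.
    peaks : per-curve frequency of the detected local maximum (nan if none).
    """

    def __init__(self, cutoff, radii, curves, peaks):
        self.cutoff = cutoff
        self.radii = radii
        self.curves = curves
        self.peaks = peaks

    def __repr__(self):
        return f"ResolutionEstimate(cutoff={self.cutoff:.3f})"


def _decorr_curve(I: np.ndarray, In: np.ndarray, r_edges_idx, norm_I: float,
                  cum_In2, order) -> np.ndarray:
    """Decorrelation d(r) for all radii via cumulative sums over sorted |k|."""
    prod = np.real(I * np.conj(In)).ravel()[order]
    cum_prod = np.concatenate([[0.0], np.cumsum(prod)])
    num = cum_prod[r_edges_idx]
    den = norm_I * np.sqrt(cum_In2[r_edges_idx])
    with np.errstate(invalid="ignore", divide="ignore"):
        d = np.where(den > 0, num / den, 0.0)
    return d


def _local_max_freq(d: np.ndarray, radii: np.ndarray) -> float:
    """Frequency of the highest local maximum of a decorrelation curve."""
    if len(d) < 3:
        return float("nan")
    interior = (d[1:-1] >= d[:-2]) & (d[1:-1] > d[2:])
    idx = np.flatnonzero(interior) + 1
    # require the peak to stand above the following minimum by a small margin
    good = []
    for i in idx:
        trailing_min = d[i:].min()
        if d[i] - trailing_min > 1e-3 and d[i] > 0:
            good.append(i)
    # a curve still rising at Nyquist peaks at the boundary (full-band image)
    if d[-1] > d[-2] and d[-1] > 0:
        good.append(len(d) - 1)
    if not good:
        return float("nan")
    return float(radii[max(good)])


def decorrelation_cutoff(
    img: np.ndarray,
    n_radii: int = 50,
    n_highpass: int = 10,
    sigma_range: tuple[float, float] = (0.15, 5.0),
    apodize: bool = True,
) -> ResolutionEstimate:
    """Estimate the spatial-frequency cutoff of a single-channel image.

    Parameter-free in the sense that no noise model or PSF is assumed; the
    image should be at least 128x128 for a stable estimate. The result is
    invariant to intensity scaling and offset by construction (mean removal
    and spectrum normalisation).
    """
    img = np.asarray(img, float)
    if img.ndim != 2:
        raise ValueError("decorrelation analysis expects a single-channel image")
    img = img - img.mean()
    if np.all(img == 0):
        return ResolutionEstimate(float("nan"), np.linspace(0, 1, n_radii),
                                  np.zeros((n_highpass + 1, n_radii)), [])
    if apodize:
        wy = np.hanning(img.shape[0])
        wx = np.hanning(img.shape[1])
        img = img * np.outer(wy, wx)

    I0 = np.fft.fftshift(np.fft.fft2(img))
    absI = np.abs(I0)
    In = np.where(absI > 0, I0 / np.maximum(absI, 1e-30), 0.0)

    fy = np.fft.fftshift(np.fft.fftfreq(img.shape[0]))
    fx = np.fft.fftshift(np.fft.fftfreq(img.shape[1]))
    FX, FY = np.meshgrid(fx, fy)
    rho = (np.hypot(FX, FY) / 0.5).ravel()  # fraction of Nyquist
    order = np.argsort(rho, kind="stable")
    rho_sorted = rho[order]
    radii = np.linspace(1.0 / n_radii, 1.0, n_radii)
    r_edges_idx = np.searchsorted(rho_sorted, radii, side="right")

    In2 = (np.abs(In) ** 2).ravel()[order]
    cum_In2 = np.concatenate([[0.0], np.cumsum(In2)])

    sigmas = np.geomspace(sigma_range[0], sigma_range[1], n_highpass)
    curves = np.empty((n_highpass + 1, n_radii))
    peaks = []
    # unfiltered curve first, then high-pass filtered versions
    variants = [img] + [img - ndi.gaussian_filter(img, s) for s in sigmas[::-1]]
    for j, im in enumerate(variants):
        I = I0 if j == 0 else np.fft.fftshift(np.fft.fft2(im))
        normI = np.linalg.norm(I)
        curves[j] = _decorr_curve(I, In, r_edges_idx, normI, cum_In2, order)
        peaks.append(_local_max_freq(curves[j], radii))

    finite = [p for p in peaks if np.isfinite(p)]
    cutoff = max(finite) if finite else float("nan")
    return ResolutionEstimate(cutoff, radii, curves, peaks)


def cutoff_heatmap(img: np.ndarray, patch: int = 128, normalize: bool = True,
                   **decorr_kw) -> np.ndarray:
    """Patchwise decorrelation cutoff over a field (min–max normalised map)."""
    img = np.asarray(img, float)
    ny, nx = img.shape[0] // patch, img.shape[1] // patch
    out = np.full((ny, nx), np.nan)
    for i in range(ny):
        for j in range(nx):
            est = decorrelation_cutoff(
                img[i * patch:(i + 1) * patch, j * patch:(j + 1) * patch], **decorr_kw
            )
            out[i, j] = est.cutoff
    if normalize and np.isfinite(out).any():
        lo, hi = np.nanmin(out), np.nanmax(out)
        if hi > lo:
            out = (out - lo) / (hi - lo)
        else:
            out = np.zeros_like(out)
    return out


def welch_t(sample_a, sample_b) -> tuple[float, float, float]:
    """Welch's unequal-variance t test: returns (t, df, two-sided p)."""
    a = np.asarray(sample_a, float)
    b = np.asarray(sample_b, float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least 2 observations per sample")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        if np.allclose(a.mean(), b.mean()):
            return 0.0, float(len(a) + len(b) - 2), 1.0
        raise ValueError("zero variance in both samples with unequal means")
    res = stats.ttest_ind(a, b, equal_var=False)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    return float(res.statistic), float(df), float(res.pvalue)


def patch_metrics(
    x: np.ndarray,
    y: np.ndarray,
    patch: int = 256,
    R: float = 1.0,
    mask: np.ndarray | None = None,
    metrics: tuple[str, ...] = ("ssim", "rmse", "psnr", "pcc"),
) -> dict:
    """Per-patch similarity metrics over a non-overlapping grid.

    ``mask`` (e.g. a tissue mask) restricts evaluation to patches with at
    least half their pixels inside the mask. Returns per-metric value lists
    plus mean ± sd summaries.
    """
    gx, gy = to_gray(x), to_gray(y)
    if gx.shape != gy.shape:
        raise ValueError("images must share a pixel grid")
    fns = {"ssim": lambda a, b: ssim(a, b, R), "rmse": rmse,
           "psnr": lambda a, b: psnr(a, b, R), "pcc": pcc}
    vals: dict[str, list] = {m: [] for m in metrics}
    coords = []
    for i in range(0, gx.shape[0] - patch + 1, patch):
        for j in range(0, gx.shape[1] - patch + 1, patch):
            if mask is not None and mask[i:i + patch, j:j + patch].mean() < 0.5:
                continue
            a, b = gx[i:i + patch, j:j + patch], gy[i:i + patch, j:j + patch]
            coords.append((i, j))
            for m in metrics:
                try:
                    vals[m].append(fns[m](a, b))
                except ValueError:
                    vals[m].append(float("nan"))
    summary = {m: (float(np.nanmean(v)) if v else float("nan"),
                   float(np.nanstd(v)) if v else float("nan")) for m, v in vals.items()}
    return {"values": vals, "summary": summary, "coords": coords,
            "params": {"patch": patch, "R": R,
                       "C1": (0.01 * R) ** 2, "C2": (0.03 * R) ** 2}}
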