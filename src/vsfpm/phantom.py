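"""Synthetic thin-section tissue phantoms and their H&E rendering.

The generator emulates the content of a colonic-mucosa section as seen by a
quantitative phase microscope: crypts rendered as annular epithelial
structures lined with ellipsoidal nuclei, scattered stromal nuclei, and
band-limited stromal texture. Nuclei are assigned a *lower* phase than the
surrounding cytoplasm, reflecting the lower refractive index of the nucleus,
which is what makes them stand out in phase images and learnable as
hematoxylin targets.

The chemical-stain renderer uses a Beer–Lambert model with fixed
hematoxylin/eosin absorbance unit vectors (Ruifrok–Johnston-style); the
phase of the "stained" section is a blurred, contrast-reduced copy of the
unstained phase, emulating the degradation that staining chemistry causes in
phase images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import _geometry

__all__ = [
    "TissuePhantom",
    "StainedPhantom",
    "generate_phantom",
    "render_hne",
    "misalign",
    "HEMATOXYLIN_OD",
    "EOSIN_OD",
]

# Normalised optical-density unit vectors (R, G, B) for the two stains.
HEMATOXYLIN_OD = np.array([0.650, 0.704, 0.286])
EOSIN_OD = np.array([0.092, 0.954, 0.283])


@dataclass
class TissuePhantom:
    """Complex transmission of a synthetic thin tissue section."""

    amplitude: np.ndarray  # [0, 1]
    phase: np.ndarray  # radians
    nucleus_mask: np.ndarray  # bool
    tissue_mask: np.ndarray  # bool
    pixel_size: float  # μm
    seed: int
    params: dict = field(default_factory=dict)

    @property
    def field(self) -> np.ndarray:
        """Complex transmission a = A * exp(i phi)."""
        return self.amplitude * np.exp(1j * self.phase)

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


@dataclass
class StainedPhantom:
    """Brightfield rendering of a phantom after simulated H&E staining."""

    rgb: np.ndarray  # (H, W, 3) in [0, 1]
    phase_stained: np.ndarray  # radians
    optical_density: np.ndarray  # (H, W, 3)
    provenance: dict = field(default_factory=dict)


def _bandlimited_noise(rng, shape, cutoff_frac: float) -> np.ndarray:
    """Zero-mean unit-std noise with spectrum limited to a fraction of Nyquist."""
    noise = rng.standard_normal(shape)
    if cutoff_frac < 1.0:
        fy = np.fft.fftfreq(shape[0])
        fx = np.fft.fftfreq(shape[1])
        FX, FY = np.meshgrid(fx, fy)
        mask = np.hypot(FX, FY) <= 0.5 * cutoff_frac
        noise = np.fft.ifft2(np.fft.fft2(noise) * mask).real
    std = noise.std()
    return noise / std if std > 0 else noise


def _draw_ellipse(mask: np.ndarray, cy, cx, a, b, angle) -> None:
    """Rasterise a filled rotated ellipse into a boolean mask, in place."""
    h, w = mask.shape
    r = int(np.ceil(max(a, b))) + 1
    y0, y1 = max(0, int(cy) - r), min(h, int(cy) + r + 1)
    x0, x1 = max(0, int(cx) - r), min(w, int(cx) + r + 1)
    if y0 >= y1 or x0 >= x1:
        return
    yy, xx = np.mgrid[y0:y1, x0:x1]
    dy, dx = yy - cy, xx - cx
    c, s = np.cos(angle), np.sin(angle)
    u = c * dx + s * dy
    v = -s * dx + c * dy
    mask[y0:y1, x0:x1] |= (u / a) ** 2 + (v / b) ** 2 <= 1.0


def generate_phantom(
    shape: tuple[int, int] = (512, 512),
    pixel_size: float = 0.3,
    n_crypts: int = 4,
    nucleus_density: float = 8.0,
    phase_scale: float = 1.5,
    texture_params: dict | None = None,
    seed: int = 0,
) -> TissuePhantom:
    """Generate a seeded synthetic tissue section.

    Parameters
    ----------
    shape : (H, W), at least 64 x 64 pixels.
    pixel_size : sample-plane pixel size in μm.
    n_crypts : number of crypt (annulus + lumen) structures to place.
    nucleus_density : stromal nuclei per 1000 μm² of tissue.
    phase_scale : peak cytoplasm phase in radians; kept modest (default
        1.5 rad) so the section stays in the thin-object regime assumed by
        the capture model.
    texture_params : dict with keys ``cutoff_frac`` (texture band limit as a
        fraction of grid Nyquist, default 0.6) and ``strength`` (phase
        texture std as a fraction of phase_scale, default 0.15).
    """
    h, w = shape
    if h < 64 or w < 64:
        raise ValueError("phantom must be at least 64 x 64 pixels")
    if phase_scale <= 0:
        raise ValueError("phase_scale must be positive")
    tp = {"cutoff_frac": 0.6, "strength": 0.15}
    tp.update(texture_params or {})
    rng = np.random.default_rng(seed)

    # tissue blob: thresholded low-pass noise, biased so ~70% of the field is
    # tissue with an irregular boundary and some clear background
    blob = _bandlimited_noise(rng, shape, 0.04)
    blob = ndi.gaussian_filter(blob, min(h, w) / 16)
    blob /= max(blob.std(), 1e-12)
    tissue = blob > np.quantile(blob, 0.3)
    tissue = ndi.binary_closing(tissue, iterations=2)

    nucleus = np.zeros(shape, dtype=bool)
    lumen = np.zeros(shape, dtype=bool)

    # crypts: annuli of epithelial nuclei around an empty lumen
    crypt_r_um = 18.0
    crypt_r = crypt_r_um / pixel_size
    if 2.2 * crypt_r >= min(h, w):
        crypt_r = min(h, w) / 2.5
        if n_crypts > 0:
            warnings.warn("field too small for the nominal crypt size; "
                          f"shrinking crypts to radius {crypt_r * pixel_size:.1f} μm",
                          stacklevel=2)
    centers: list[tuple[float, float]] = []
    placed = 0
    for _ in range(n_crypts):
        ok = False
        for _attempt in range(50):
            cy = rng.uniform(crypt_r, h - crypt_r)
            cx = rng.uniform(crypt_r, w - crypt_r)
            if not tissue[int(cy), int(cx)]:
                continue
            if all(np.hypot(cy - py, cx - px) > 2.2 * crypt_r for py, px in centers):
                ok = True
                break
        if not ok:
            continue
        centers.append((cy, cx))
        placed += 1
        r_lumen = crypt_r * rng.uniform(0.4, 0.55)
        _draw_ellipse(lumen, cy, cx, r_lumen, r_lumen * rng.uniform(0.8, 1.0), rng.uniform(0, np.pi))
        n_ring = max(8, int(2 * np.pi * crypt_r * 0.75 * pixel_size / 4.5))
        for t in np.linspace(0, 2 * np.pi, n_ring, endpoint=False):
            rr = crypt_r * rng.uniform(0.68, 0.82)
            ny_, nx_ = cy + rr * np.sin(t), cx + rr * np.cos(t)
            # epithelial nuclei: elongated, radially oriented
            _draw_ellipse(
                nucleus, ny_, nx_,
                3.2 / pixel_size * rng.uniform(0.8, 1.2),
                1.6 / pixel_size * rng.uniform(0.8, 1.2),
                t + np.pi / 2 + rng.normal(0, 0.2),
            )
    if n_crypts > 0 and placed == 0:
        raise ValueError("could not place any crypt; reduce n_crypts or crypt size")
    if placed < n_crypts:
        warnings.warn(f"placed only {placed}/{n_crypts} crypts without overlap", stacklevel=2)

    # scattered stromal nuclei
    area_um2 = tissue.sum() * pixel_size**2
    n_stromal = rng.poisson(nucleus_density * area_um2 / 1000.0) if nucleus_density > 0 else 0
    for _ in range(n_stromal):
        cy, cx = rng.uniform(0, h), rng.uniform(0, w)
        if not tissue[int(cy) % h, int(cx) % w]:
            continue
        _draw_ellipse(
            nucleus, cy, cx,
            2.6 / pixel_size * rng.uniform(0.7, 1.3),
            1.7 / pixel_size * rng.uniform(0.7, 1.3),
            rng.uniform(0, np.pi),
        )
    nucleus &= tissue
    lumen &= tissue
    nucleus &= ~lumen

    # phase: cytoplasm above nuclei above lumen/background, plus texture
    texture = _bandlimited_noise(rng, shape, tp["cutoff_frac"]) * tp["strength"] * phase_scale
    phase = np.zeros(shape)
    cyto = tissue & ~nucleus & ~lumen
    phase[cyto] = 0.75 * phase_scale
    phase[nucleus] = 0.45 * phase_scale
    phase[lumen] = 0.15 * phase_scale
    phase = ndi.gaussian_filter(phase, 1.2 / pixel_size * 0.5)
    phase += texture
    phase[~tissue] = 0.0

    amplitude = np.ones(shape)
    amplitude[tissue] = 0.93
    amplitude += 0.03 * texture / max(tp["strength"] * phase_scale, 1e-12) * tissue
    amplitude = ndi.gaussian_filter(amplitude, 0.8)
    amplitude[~tissue] = 1.0
    amplitude = np.clip(amplitude, 0.0, 1.0)

    return TissuePhantom(
        amplitude=amplitude,
        phase=phase,
        nucleus_mask=nucleus,
        tissue_mask=tissue,
        pixel_size=pixel_size,
        seed=seed,
        params={
            "shape": shape, "pixel_size": pixel_size, "n_crypts": n_crypts,
            "nucleus_density": nucleus_density, "phase_scale": phase_scale,
            "texture_params": tp,
        },
    )


def render_hne(
    ph: TissuePhantom,
    hematoxylin: float = 1.0,
    eosin: float = 0.35,
    nuclear_eosin: float = 0.10,
    phase_blur_px: float = 2.0,
    phase_contrast: float = 0.6,
) -> StainedPhantom:
    """Render the chemically H&E-stained counterpart of a phantom.

    Transmission follows Beer–Lambert: ``rgb = exp(-OD)`` with
    ``OD = c_h * A_h + c_e * A_e``, hematoxylin concentration on the nucleus
    mask and eosin on the remaining tissue (a weak eosin term also stains
    nuclei). Background pixels carry zero concentration and render exactly
    white. ``phase_stained`` is the unstained phase Gaussian-blurred by
    ``phase_blur_px`` and scaled by ``phase_contrast``, emulating the loss of
    fine detail and contrast that chemical staining causes in phase images.
    """
    c_h = np.where(ph.nucleus_mask, float(hematoxylin), 0.0)
    c_e = np.where(ph.tissue_mask, float(eosin), 0.0)
    c_e = np.where(ph.nucleus_mask, float(nuclear_eosin), c_e)
    od = c_h[..., None] * HEMATOXYLIN_OD + c_e[..., None] * EOSIN_OD
    # light modulation by local texture so the stain image is not piecewise flat
    mod = 1.0 + 0.35 * (1.0 - ph.amplitude) / 0.07
    od = od * np.where(ph.tissue_mask, mod, 1.0)[..., None]
    rgb = np.exp(-od)

    phase_stained = ndi.gaussian_filter(ph.phase, phase_blur_px) * float(phase_contrast)
    return StainedPhantom(
        rgb=rgb,
        phase_stained=phase_stained,
        optical_density=od,
        provenance={
            "seed": ph.seed, "phantom_params": ph.params,
            "hematoxylin": hematoxylin, "eosin": eosin,
            "nuclear_eosin": nuclear_eosin,
            "phase_blur_px": phase_blur_px, "phase_contrast": phase_contrast,
        },
    )


def misalign(
    img: np.ndarray,
    homography: np.ndarray | None = None,
    distortion_params: dict | None = None,
    order: int = 1,
):
    """Warp an image by a known transform and return (warped, ground truth).

    Exactly one of ``homography`` (3x3 source->destination matrix) or
    ``distortion_params`` (Brown–Conrady ``k1, k2, p1, p2, center, focal``)
    must be given. The returned ground-truth transform lets registration and
    undistortion tests score their recovery exactly.
    """
    if (homography is None) == (distortion_params is None):
        raise ValueError("give exactly one of homography or distortion_params")
    if homography is not None:
        warped = _geometry.warp_homography(np.asarray(img, float), homography, order=order)
        return warped, np.asarray(homography, dtype=np.float64)
    params = dict(distortion_params)
    params.setdefault("center", ((img.shape[1] - 1) / 2.0, (img.shape[0] - 1) / 2.0))
    params.setdefault("focal", min(img.shape[:2]) / 2.0)
    coords = _geometry.distortion_grid(img.shape[:2], inverse=False, **params)
    warped = _geometry.resample(np.asarray(img, float), coords, order=order)
    return warped, params
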