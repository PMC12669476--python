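"""Phase retrieval and post-processing of FPM stacks.

The solver is the sequential Gauss–Newton scheme: for each LED the current
object estimate is propagated through the forward model, the measured
modulus replaces the modelled one, and the residual is back-propagated into
the object spectrum (and optionally the pupil) with regularised second-order
step sizes ``conj(P)/(max|P|^2 + alpha)`` / ``conj(O)/(max|O|^2 + beta)``.
LEDs are visited from low to high illumination frequency so the low-order
spectrum stabilises before darkfield updates extend it.

Post-processing mirrors the standard FPM pipeline: per-patch phase
flattening (mean/std normalisation minus a Gaussian-blurred copy),
histogram matching of reconstructed amplitude to the brightfield sum,
grid stitching with linear blending, Brown–Conrady undistortion, and
angular-spectrum digital refocusing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from . import _geometry
from .forward import FPMStack, brightfield_sum, k_to_pixel_shifts, lowres_field
from .optics import LEDPlan, Pupil

__all__ = [
    "ComplexField",
    "ReconConfig",
    "gauss_newton_reconstruct",
    "digital_refocus",
    "phase_flatten",
    "amplitude_match",
    "stitch",
    "undistort",
    "fourier_upsample",
    "align_global_phase",
    "nrmse",
    "bandlimit",
]


@dataclass
class ComplexField:
    """Reconstructed complex object on a stated pixel grid."""

    amplitude: np.ndarray  # >= 0
    phase: np.ndarray  # radians, (-pi, pi]
    pixel_size: float  # μm
    na_limit: float  # band limit of validity (NA units)
    wavelength: float  # nm
    provenance: dict = field(default_factory=dict)

    @property
    def field(self) -> np.ndarray:
        return self.amplitude * np.exp(1j * self.phase)

    @classmethod
    def from_complex(cls, z: np.ndarray, pixel_size: float, na_limit: float,
                     wavelength: float, **prov) -> "ComplexField":
        return cls(np.abs(z), np.angle(z), pixel_size, na_limit, wavelength, dict(prov))

    @property
    def shape(self) -> tuple[int, int]:
        return self.amplitude.shape


@dataclass
class ReconConfig:
    """Reconstruction parameters.

    ``patch_size_raw`` and ``upsample`` follow the standard patchwise scheme
    (243-px raw patches upsampled 3x); ``alpha``/``beta`` are the relative
    Gauss–Newton regularisers (scaled by the running ``max|.|^2``).
    """

    patch_size_raw: int = 243
    upsample: int = 3
    n_iters: int = 10
    update_order: str = "low_to_high"  # or "plan"
    alpha: float = 1e-3
    beta: float = 1e-3
    pupil_recovery: bool = False
    blur_kernel_px: int = 31
    patch_overlap: float = 0.25

    def __post_init__(self) -> None:
        if self.patch_size_raw < 64:
            raise ValueError("patch_size_raw must be at least 64")
        if self.upsample < 1:
            raise ValueError("upsample must be a positive integer")


def fourier_upsample(img: np.ndarray, factor: int) -> np.ndarray:
    """Ideal (sinc) upsampling by zero-padding the spectrum; preserves mean."""
    if factor == 1:
        return np.asarray(img, float).copy()
    h, w = img.shape
    spec = np.fft.fftshift(np.fft.fft2(img, norm="ortho"))
    big = np.zeros((h * factor, w * factor), dtype=complex)
    cy, cx = (h * factor) // 2, (w * factor) // 2
    big[cy - h // 2 : cy - h // 2 + h, cx - w // 2 : cx - w // 2 + w] = spec
    out = np.fft.ifft2(np.fft.ifftshift(big), norm="ortho") * factor
    return out.real if np.isrealobj(img) else out


def align_global_phase(z: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Remove the global phase/scale gauge: least-squares complex scalar fit.

    Reconstructions are defined up to a global complex factor; comparisons
    against ground truth are made after this alignment.
    """
    c = np.vdot(z, ref) / max(np.vdot(z, z).real, 1e-30)
    return z * c


def nrmse(a: np.ndarray, ref: np.ndarray) -> float:
    """Normalised RMS error ||a - ref|| / ||ref||."""
    return float(np.linalg.norm(a - ref) / np.linalg.norm(ref))


def bandlimit(z: np.ndarray, pixel_size: float, f_cutoff: float) -> np.ndarray:
    """Zero all spatial frequencies above ``f_cutoff`` (cycles/μm)."""
    fy = np.fft.fftfreq(z.shape[0], d=pixel_size)
    fx = np.fft.fftfreq(z.shape[1], d=pixel_size)
    FX, FY = np.meshgrid(fx, fy)
    mask = FX**2 + FY**2 <= f_cutoff**2 + 1e-12
    return np.fft.ifft2(np.fft.fft2(z) * mask)


def gauss_newton_reconstruct(
    stack: FPMStack,
    pupil: Pupil,
    cfg: ReconConfig | None = None,
) -> tuple[ComplexField, Pupil]:
    """Recover the complex object (and optionally the pupil) from a stack.

    Returns the reconstructed field on the ``upsample``-times finer grid and
    the final pupil estimate. The monitored data misfit per epoch,
    ``sum_n sum_px (sqrt(I_model) - sqrt(I_obs))^2``, is stored in the field
    provenance; if it increases for 3 consecutive epochs the best iterate is
    returned with a warning.
    """
    cfg = cfg or ReconConfig()
    plan = stack.plan
    if len(stack.frames) != len(plan):
        raise ValueError("stack frame count does not match plan")
    ups = cfg.upsample
    nraw = stack.sensor_shape
    nobj = (nraw[0] * ups, nraw[1] * ups)
    px_raw = stack.pixel_size_obj * stack.downsample_factor
    px_obj = px_raw / ups

    lam_um = stack.wavelength * 1e-3
    na_syn = pupil.cutoff * lam_um + plan.sin_theta_max
    if 0.5 / px_obj < na_syn / lam_um:
        raise ValueError("upsample too small: output Nyquist below NA_syn band")

    intensities = stack.rescaled() / stack.gain
    amps = np.sqrt(np.maximum(intensities, 0.0))

    shifts, _ = k_to_pixel_shifts(plan, nobj, px_obj)
    order = np.argsort(np.hypot(*plan.k_illum.T), kind="stable") \
        if cfg.update_order == "low_to_high" else np.arange(len(plan))

    # initialise from the most axial frame, ideally upsampled, zero phase
    i0 = int(order[0])
    obj0 = fourier_upsample(amps[i0], ups).astype(np.complex128)
    spec = np.fft.fftshift(np.fft.fft2(obj0, norm="ortho"))
    P = np.fft.fftshift(pupil.grid.copy())
    aperture = np.fft.fftshift(pupil.aperture)
    scale = np.sqrt(nraw[0] * nraw[1] / (nobj[0] * nobj[1]))

    def window(i):
        cy, cx = nobj[0] // 2, nobj[1] // 2
        sy, sx = shifts[i]
        return (slice(cy - nraw[0] // 2 + sy, cy - nraw[0] // 2 + sy + nraw[0]),
                slice(cx - nraw[1] // 2 + sx, cx - nraw[1] // 2 + sx + nraw[1]))

    misfit_hist: list[float] = []
    best = (np.inf, spec.copy(), P.copy())
    n_rising = 0
    for _epoch in range(cfg.n_iters):
        misfit = 0.0
        for i in order:
            wy, wx = window(i)
            W = spec[wy, wx]
            Phi = P * W
            psi = np.fft.ifft2(np.fft.ifftshift(Phi), norm="ortho") * scale
            mod = np.abs(psi)
            misfit += float(np.sum((mod - amps[i]) ** 2))
            psi_new = amps[i] * psi / np.maximum(mod, 1e-12)
            Phi_new = np.fft.fftshift(np.fft.fft2(psi_new, norm="ortho")) / scale
            dPhi = (Phi_new - Phi) * aperture
            w_old = W.copy()
            spec[wy, wx] += np.conj(P) * dPhi / (np.abs(P).max() ** 2 * (1 + cfg.alpha))
            if cfg.pupil_recovery:
                P += np.conj(w_old) * dPhi / (np.abs(w_old).max() ** 2 * (1 + cfg.beta))
                P *= aperture
        misfit_hist.append(misfit)
        if misfit <= best[0] * (1 + 1e-9) + 1e-12:
            if misfit < best[0]:
                best = (misfit, spec.copy(), P.copy())
            n_rising = 0
        else:
            n_rising += 1
            if n_rising >= 3:
                warnings.warn("data misfit increased for 3 consecutive epochs; "
                              "returning best iterate", stacklevel=2)
                _, spec, P = best
                break

    obj = np.fft.ifft2(np.fft.ifftshift(spec), norm="ortho")
    fld = ComplexField.from_complex(
        obj, px_obj, na_limit=na_syn, wavelength=stack.wavelength,
        misfit_per_epoch=misfit_hist, n_iters=cfg.n_iters, upsample=ups,
        pupil_recovery=cfg.pupil_recovery,
    )
    pupil_out = Pupil(
        grid=np.fft.ifftshift(P), cutoff=pupil.cutoff, fx=pupil.fx, fy=pupil.fy,
        defocus=pupil.defocus, zernike_coeffs=dict(pupil.zernike_coeffs),
    )
    return fld, pupil_out


def digital_refocus(fld: ComplexField, z: float, wavelength: float | None = None) -> ComplexField:
    """Propagate the reconstructed field by ``z`` μm (angular spectrum).

    Within the propagating band the transfer function is the pure phase
    ``exp(i 2π/λ z sqrt(1 − λ²k²))``, so ``refocus(z)`` composed with
    ``refocus(-z)`` is the identity. A warning is raised when |z| exceeds the
    DOF-scale validity ``λ/NA_limit²``.
    """
    lam_um = (wavelength or fld.wavelength) * 1e-3
    if fld.na_limit > 0 and abs(z) > 2 * lam_um / fld.na_limit**2:
        warnings.warn("refocus distance far beyond the depth-of-field scale", stacklevel=2)
    fy = np.fft.fftfreq(fld.shape[0], d=fld.pixel_size)
    fx = np.fft.fftfreq(fld.shape[1], d=fld.pixel_size)
    FX, FY = np.meshgrid(fx, fy)
    k2 = lam_um**2 * (FX**2 + FY**2)
    kz = np.sqrt(np.maximum(0.0, 1.0 - k2))
    H = np.where(k2 <= 1.0, np.exp(1j * 2 * np.pi / lam_um * z * kz), 1.0)
    out = np.fft.ifft2(np.fft.fft2(fld.field) * H)
    prov = dict(fld.provenance)
    prov["refocus_um"] = prov.get("refocus_um", 0.0) + z
    return ComplexField.from_complex(out, fld.pixel_size, fld.na_limit, fld.wavelength, **prov)


def phase_flatten(patch: np.ndarray, blur_kernel_px: int = 31) -> tuple[np.ndarray, bool]:
    """Remove scalar offsets and slow gradients from a phase patch.

    The patch is normalised (subtract mean, divide by std) and a Gaussian
    blur of the stated kernel size is subtracted, driving background regions
    to ~0. Returns ``(corrected, ok)``; a constant patch yields zeros with
    ``ok=False``.
    """
    patch = np.asarray(patch, float)
    std = patch.std()
    if std == 0:
        return np.zeros_like(patch), False
    p = (patch - patch.mean()) / std
    sigma = blur_kernel_px / 6.0
    radius = (blur_kernel_px - 1) // 2
    blurred = ndi.gaussian_filter(p, sigma, truncate=radius / sigma)
    return p - blurred, True


def _match_cdf(src: np.ndarray, ref: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Monotone remap of src so its n_bins histogram matches ref's."""
    lo_s, hi_s = src.min(), src.max()
    if hi_s == lo_s:
        return np.full_like(src, ref.mean())
    edges_s = np.linspace(lo_s, hi_s, n_bins + 1)
    lo_r, hi_r = ref.min(), ref.max()
    edges_r = np.linspace(lo_r, hi_r if hi_r > lo_r else lo_r + 1, n_bins + 1)
    hist_s, _ = np.histogram(src, bins=edges_s)
    hist_r, _ = np.histogram(ref, bins=edges_r)
    cdf_s = np.cumsum(hist_s) / src.size
    cdf_r = np.cumsum(hist_r) / ref.size
    # value each source bin should map to: inverse ref CDF at the source CDF
    ref_values = np.interp(cdf_s, np.concatenate([[0], cdf_r]),
                           np.concatenate([[edges_r[0]], edges_r[1:]]))
    idx = np.clip(np.digitize(src, edges_s[1:-1]), 0, n_bins - 1)
    return ref_values[idx]


def amplitude_match(high_res: np.ndarray, brightfield_low: np.ndarray,
                    n_bins: int = 256) -> np.ndarray:
    """Histogram-match a reconstructed amplitude patch to its brightfield patch.

    Corrects slowly varying intensity errors in the reconstruction by forcing
    the amplitude histogram onto that of the (trusted) brightfield sum of the
    same field region; the reference needs no resampling because only its
    histogram is used.
    """
    return _match_cdf(np.asarray(high_res, float), np.asarray(brightfield_low, float), n_bins)


def histogram_match_gray(src: np.ndarray, ref: np.ndarray, n_bins: int = 256) -> np.ndarray:
    """Alias of the amplitude-matching remap for generic grayscale images."""
    return _match_cdf(np.asarray(src, float), np.asarray(ref, float), n_bins)


def stitch(
    patches,
    offsets,
    blend: str = "linear",
    refine_px: int = 0,
) -> np.ndarray:
    """Assemble patches at (row, col) offsets into one field with blending.

    Overlapping regions are combined with separable linear ramp weights
    ("linear") or uniform averaging ("mean"). With ``refine_px`` > 0 each
    patch's nominal offset is refined by phase correlation against the canvas
    built so far, searched within ±refine_px (requires overlap).
    """
    from skimage.registration import phase_cross_correlation

    patches = [np.asarray(p, float) for p in patches]
    offsets = [np.asarray(o, float) for o in offsets]
    if len(patches) != len(offsets):
        raise ValueError("need one offset per patch")
    if len(patches) == 1 and refine_px == 0:
        return patches[0].copy()

    off = np.array([np.round(o).astype(int) for o in offsets])
    off -= off.min(axis=0)

    def ramp(n):
        r = np.minimum(np.arange(n) + 1, np.arange(n)[::-1] + 1).astype(float)
        return r / r.max()

    shapes = np.array([p.shape for p in patches])
    canvas_shape = tuple((off + shapes).max(axis=0))
    acc = np.zeros(canvas_shape)
    wacc = np.zeros(canvas_shape)

    order = np.lexsort((off[:, 1], off[:, 0]))
    for j, i in enumerate(order):
        p = patches[i]
        oy, ox = off[i]
        if refine_px > 0 and j > 0:
            sl = (slice(oy, oy + p.shape[0]), slice(ox, ox + p.shape[1]))
            placed = wacc[sl] > 0
            if not placed.any():
                raise ValueError("refinement requested but patch has no overlap")
            ref_img = np.where(placed, acc[sl] / np.maximum(wacc[sl], 1e-12), p)
            shift, _, _ = phase_cross_correlation(ref_img, p, upsample_factor=1,
                                                  normalization=None)
            dy, dx = np.clip(np.round(shift).astype(int), -refine_px, refine_px)
            oy, ox = np.clip(oy + dy, 0, canvas_shape[0] - p.shape[0]), \
                     np.clip(ox + dx, 0, canvas_shape[1] - p.shape[1])
        w = (np.outer(ramp(p.shape[0]), ramp(p.shape[1]))
             if blend == "linear" else np.ones(p.shape))
        acc[oy:oy + p.shape[0], ox:ox + p.shape[1]] += p * w
        wacc[oy:oy + p.shape[0], ox:ox + p.shape[1]] += w
    out = acc / np.maximum(wacc, 1e-12)
    out[wacc == 0] = 0.0
    return out


def undistort(
    image: np.ndarray,
    k1: float = 0.0,
    k2: float = 0.0,
    p1: float = 0.0,
    p2: float = 0.0,
    center: tuple[float, float] | None = None,
    focal: float | None = None,
    order: int = 1,
) -> np.ndarray:
    """Correct Brown–Conrady radial/tangential distortion (bilinear resampling)."""
    image = np.asarray(image, float)
    if center is None:
        center = ((image.shape[1] - 1) / 2.0, (image.shape[0] - 1) / 2.0)
    if focal is None:
        focal = min(image.shape[:2]) / 2.0
    if k1 == k2 == p1 == p2 == 0.0:
        return image.copy()
    coords = _geometry.distortion_grid(
        image.shape[:2], inverse=True, k1=k1, k2=k2, p1=p1, p2=p2,
        center=center, focal=focal,
    )
    return _geometry.resample(image, coords, order=order)


def reconstruct_patchwise(
    stack: FPMStack,
    pupil_factory,
    cfg: ReconConfig | None = None,
) -> ComplexField:
    """Patchwise reconstruction: crop the stack into raw patches with overlap,
    reconstruct each, flatten phase / match amplitude, and stitch.

    ``pupil_factory(shape)`` must return a Pupil for a raw patch grid of the
    given shape. Patch cropping of the raw frames is an approximation at the
    patch borders (the forward model is not spatially separable), which is
    exactly why overlap-and-blend stitching is used.
    """
    cfg = cfg or ReconConfig()
    n = cfg.patch_size_raw
    H, W = stack.sensor_shape
    step = max(1, int(n * (1 - cfg.patch_overlap)))
    ys = sorted({min(y, H - n) for y in range(0, H, step) if H >= n} or {0})
    xs = sorted({min(x, W - n) for x in range(0, W, step) if W >= n} or {0})

    amp_patches, ph_patches, offs = [], [], []
    bf = brightfield_sum(stack)
    na_limit = 0.0
    for y in ys:
        for x in xs:
            sub = FPMStack(
                frames=stack.frames[:, y:y + n, x:x + n].copy(),
                plan=stack.plan, exposure=stack.exposure,
                wavelength=stack.wavelength,
                downsample_factor=stack.downsample_factor,
                pixel_size_obj=stack.pixel_size_obj, gain=stack.gain,
                noise_params=stack.noise_params, seed=stack.seed,
            )
            ny, nx = sub.sensor_shape
            fld, _ = gauss_newton_reconstruct(sub, pupil_factory((ny, nx)), cfg)
            na_limit = fld.na_limit
            flat, _ok = phase_flatten(fld.phase, cfg.blur_kernel_px)
            amp = amplitude_match(fld.amplitude, bf[y:y + ny, x:x + nx])
            amp_patches.append(amp)
            ph_patches.append(flat)
            offs.append((y * cfg.upsample, x * cfg.upsample))
    amp_full = stitch(amp_patches, offs)
    ph_full = stitch(ph_patches, offs)
    return ComplexField(
        amplitude=amp_full, phase=ph_full,
        pixel_size=stack.pixel_size_obj * stack.downsample_factor / cfg.upsample,
        na_limit=na_limit, wavelength=stack.wavelength,
        provenance={"patchwise": True, "patch_size_raw": n, "overlap": cfg.patch_overlap},
    )
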