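"""FPM digital camera: simulate the raw intensity stack captured per LED.

Forward model per LED ``n`` with illumination spatial frequency ``k_n``: the
tilted plane wave shifts the object spectrum, the objective pupil ``P`` cuts
out a low-NA passband, and the camera records intensity::

    psi_n = IFT{ P(k) * O(k + k_n) },   I_n = |psi_n|^2

The object lives on a fine grid (``downsample_factor`` times the sensor
pitch); the passband extraction doubles as ideal anti-aliased downsampling
(Fourier cropping). Spectrum shifts are rounded to integer pixels of the
object Fourier grid — the standard discrete FPM model — with the sub-pixel
residuals recorded in the stack metadata. All FFTs are unitary ("ortho").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .optics import LEDPlan, Pupil, rescale_intensity

__all__ = [
    "NoiseParams",
    "FPMStack",
    "k_to_pixel_shifts",
    "capture_stack",
    "brightfield_sum",
    "darkfield_ring_indices",
    "autofocus_metric",
    "autofocus",
]


@dataclass(frozen=True)
class NoiseParams:
    """Camera noise model: Poisson shot noise, Gaussian read noise, full well."""

    shot: bool = True
    read_sigma: float = 2.0  # e-
    full_well: float = 30000.0  # e-

    @classmethod
    def none(cls) -> "NoiseParams":
        return cls(shot=False, read_sigma=0.0, full_well=np.inf)


@dataclass
class FPMStack:
    """Ordered raw intensity frames (photoelectron counts), one per LED."""

    frames: np.ndarray  # (n_led, H, W)
    plan: LEDPlan
    exposure: np.ndarray  # (n_led,) ms
    wavelength: float  # nm
    downsample_factor: int
    pixel_size_obj: float  # μm, object-grid pixel
    gain: float  # photoelectrons per unit ideal intensity at T_BF
    noise_params: NoiseParams = field(default_factory=NoiseParams)
    seed: int | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(self.frames) != len(self.plan):
            raise ValueError("frame count does not match LED plan")
        if np.any(self.frames < 0):
            raise ValueError("intensities must be non-negative")

    @property
    def saturated(self) -> np.ndarray:
        return self.frames >= self.noise_params.full_well

    @property
    def sensor_shape(self) -> tuple[int, int]:
        return self.frames.shape[1:]

    def rescaled(self) -> np.ndarray:
        """Frames scaled back to the common brightfield exposure."""
        return rescale_intensity(self.frames, self.plan)


def k_to_pixel_shifts(plan: LEDPlan, n_obj: tuple[int, int], pixel_size: float):
    """Round illumination frequencies to object-Fourier-grid pixels.

    Returns integer shifts (n, 2) in (row, col) order and the sub-pixel
    residuals in cycles/μm. Row shift corresponds to ky, col to kx; the grid
    frequency step along each axis is 1/(N * pixel_size).
    """
    dfy = 1.0 / (n_obj[0] * pixel_size)
    dfx = 1.0 / (n_obj[1] * pixel_size)
    exact = np.column_stack([plan.k_illum[:, 1] / dfy, plan.k_illum[:, 0] / dfx])
    shifts = np.round(exact).astype(int)
    residual = (exact - shifts) * np.array([dfy, dfx])
    return shifts, residual


def _centered_window(n_big: int, n_small: int, shift: int) -> slice:
    c = n_big // 2
    lo = c - n_small // 2 + shift
    if lo < 0 or lo + n_small > n_big:
        raise ValueError("illumination shift pushes passband off the object grid")
    return slice(lo, lo + n_small)


def lowres_field(
    obj_spectrum_shifted: np.ndarray,
    pupil: Pupil,
    shift_rc: tuple[int, int],
    scale: float,
) -> np.ndarray:
    """Low-resolution complex field for one LED.

    ``obj_spectrum_shifted`` is the fftshifted unitary FFT of the object on
    the fine grid; ``shift_rc`` the integer spectrum shift for this LED.
    """
    nraw = pupil.grid.shape
    nbig = obj_spectrum_shifted.shape
    wy = _centered_window(nbig[0], nraw[0], shift_rc[0])
    wx = _centered_window(nbig[1], nraw[1], shift_rc[1])
    win = obj_spectrum_shifted[wy, wx] * np.fft.fftshift(pupil.grid)
    return np.fft.ifft2(np.fft.ifftshift(win), norm="ortho") * scale


def capture_stack(
    ph,
    plan: LEDPlan,
    pupil: Pupil,
    downsample_factor: int = 3,
    t_bf: float = 2.0,
    gain: float = 5000.0,
    noise_params: NoiseParams | None = None,
    seed: int = 0,
) -> FPMStack:
    """Simulate the raw FPM stack of a phantom under the given LED plan.

    ``ph`` is a :class:`~vsfpm.phantom.TissuePhantom` (or any object with
    ``field``/``pixel_size``/``shape``). ``gain`` sets the mean photoelectron
    count produced by unit intensity at the brightfield exposure ``t_bf``;
    darkfield frames integrate ``exposure_scale`` times longer and are
    therefore recorded with proportionally larger counts.
    """
    noise_params = noise_params if noise_params is not None else NoiseParams()
    obj = np.asarray(ph.field, dtype=np.complex128)
    px = float(ph.pixel_size)
    h, w = obj.shape
    if h % downsample_factor or w % downsample_factor:
        raise ValueError("object shape must be a multiple of downsample_factor")
    nraw = (h // downsample_factor, w // downsample_factor)
    if pupil.grid.shape != nraw:
        raise ValueError(f"pupil grid {pupil.grid.shape} must match sensor grid {nraw}")

    lam_um = plan.wavelength * 1e-3
    f_syn = pupil.cutoff + float(np.hypot(*plan.k_illum.T).max())
    nyq = 0.5 / px
    if f_syn > nyq:
        raise ValueError(
            f"object grid undersampled: synthetic cutoff {f_syn:.3f} cycles/μm "
            f"exceeds Nyquist {nyq:.3f}; need pixel size < {1 / (2 * f_syn):.4f} μm "
            f"(i.e. < lambda/(2 NA_syn) = {lam_um / (2 * f_syn * lam_um):.4f} μm)"
        )

    shifts, residual = k_to_pixel_shifts(plan, obj.shape, px)
    spec = np.fft.fftshift(np.fft.fft2(obj, norm="ortho"))
    scale = np.sqrt(nraw[0] * nraw[1] / (h * w))  # mean-preserving Fourier crop

    rng = np.random.default_rng(seed)
    frames = np.empty((len(plan), *nraw))
    for i in range(len(plan)):
        psi = lowres_field(spec, pupil, tuple(shifts[i]), scale)
        counts = np.abs(psi) ** 2 * gain * plan.exposure_scale[i]
        if noise_params.shot:
            counts = rng.poisson(counts).astype(np.float64)
        if noise_params.read_sigma > 0:
            counts = counts + rng.normal(0.0, noise_params.read_sigma, counts.shape)
        frames[i] = np.clip(counts, 0.0, noise_params.full_well)

    return FPMStack(
        frames=frames,
        plan=plan,
        exposure=plan.exposure_scale * t_bf,
        wavelength=plan.wavelength,
        downsample_factor=downsample_factor,
        pixel_size_obj=px,
        gain=gain,
        noise_params=noise_params,
        seed=seed,
        metadata={"k_pixel_shifts": shifts, "k_residual": residual, "t_bf": t_bf},
    )


def brightfield_sum(stack: FPMStack | np.ndarray) -> np.ndarray:
    """Pixelwise linear sum of all exposure-rescaled frames.

    This is the image an ordinary low-NA brightfield microscope with an
    extended source would record — the resolution baseline the reconstruction
    is compared against.
    """
    frames = stack.rescaled() if isinstance(stack, FPMStack) else np.asarray(stack, float)
    return frames.sum(axis=0)


def darkfield_ring_indices(plan: LEDPlan, width: float | None = None) -> np.ndarray:
    """Indices of the innermost fully-darkfield ring of LEDs.

    ``width`` (mm) sets how far beyond the innermost darkfield radius LEDs
    still count as part of the ring; default is 60% of the nearest-neighbour
    pitch inferred from the plan.
    """
    dark = ~plan.is_brightfield
    if not dark.any():
        raise ValueError("plan contains no darkfield LEDs")
    r0 = plan.radial_dist[dark].min()
    if width is None:
        uniq = np.unique(np.round(plan.radial_dist, 6))
        width = 0.6 * float(np.diff(uniq).min()) if len(uniq) > 1 else 0.0
    return np.flatnonzero(dark & (plan.radial_dist <= r0 + width + 1e-9))


def autofocus_metric(frames: np.ndarray) -> float:
    """Normalised variance ``var(I)/mean(I)^2`` of the summed darkfield image.

    Darkfield frames contain only scattered light, so their contrast is
    sharpest at focus; the metric is invariant to overall intensity scale.
    """
    frames = np.atleast_3d(np.asarray(frames, float))
    img = frames.sum(axis=0) if frames.ndim == 3 else frames
    m = img.mean()
    if m == 0:
        raise ValueError("zero-mean image: autofocus metric undefined")
    return float(img.var() / m**2)


def autofocus(frames_by_z, z_values, refine: bool = True) -> float:
    """Best focus position: argmax of the autofocus metric over a z grid.

    ``frames_by_z`` is a sequence of darkfield frame groups, one per entry of
    ``z_values``. With ``refine`` a parabola through the peak and its
    neighbours interpolates between grid points.
    """
    z_values = np.asarray(z_values, float)
    scores = np.array([autofocus_metric(f) for f in frames_by_z])
    i = int(np.argmax(scores))
    if refine and 0 < i < len(scores) - 1:
        y0, y1, y2 = scores[i - 1 : i + 2]
        denom = y0 - 2 * y1 + y2
        if denom < 0:
            delta = 0.5 * (y0 - y2) / denom
            return float(z_values[i] + delta * (z_values[min(i + 1, len(z_values) - 1)] - z_values[i]))
    return float(z_values[i])
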