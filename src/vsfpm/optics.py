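"""Optical system geometry and LED illumination planning.

Units and conventions used throughout the package:

* lengths in mm (LED geometry) and μm (pixels, wavelength-derived grids);
  wavelengths are given in nm and converted to μm internally;
* spatial frequencies in cycles/μm in sample space;
* image arrays are indexed ``(row, col)``; Fourier grids are centred on the
  zero-frequency pixel returned by :func:`numpy.fft.fftfreq`.

The key quantity of Fourier ptychography is the synthetic numerical
aperture ``NA_syn = NA_obj + sin(theta_max)``: tilting the illumination by
``theta`` shifts the object spectrum by ``sin(theta)/lambda``, so the set of
captured passbands covers a disk of radius ``NA_syn / lambda``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalSystem",
    "LEDArray",
    "LEDPlan",
    "Pupil",
    "effective_magnification",
    "build_led_plan",
    "synthetic_na",
    "depth_of_field",
    "field_of_view",
    "make_pupil",
    "exposure_schedule",
    "rescale_intensity",
]

# red / green / blue LED central wavelengths (nm)
DEFAULT_WAVELENGTHS_NM = (629.0, 530.0, 475.0)


@dataclass(frozen=True)
class OpticalSystem:
    """Objective + tube lens + camera description.

    The effective magnification of an infinity-corrected objective used with
    a non-design tube lens is ``mag_nominal * f_tube / f_reference``.
    """

    na_obj: float = 0.16
    mag_nominal: float = 4.0
    f_tube: float = 200.0  # mm
    f_reference: float = 180.0  # mm, objective design tube length
    wavelengths: tuple[float, ...] = DEFAULT_WAVELENGTHS_NM  # nm
    pixel_pitch_camera: float = 4.25  # μm
    sensor_shape: tuple[int, int] = (2960, 5056)  # (H, W) px

    def __post_init__(self) -> None:
        if not 0.0 < self.na_obj < 1.0:
            raise ValueError(f"na_obj must be in (0, 1), got {self.na_obj}")
        if self.f_tube <= 0 or self.f_reference <= 0 or self.mag_nominal <= 0:
            raise ValueError("magnification and focal lengths must be positive")

    @property
    def wavelength_green(self) -> float:
        return self.wavelengths[1] if len(self.wavelengths) > 1 else self.wavelengths[0]


@dataclass(frozen=True)
class LEDArray:
    """Planar LED matrix below the sample."""

    n_rows: int = 22
    n_cols: int = 22
    pitch: float = 7.0  # mm
    height: float = 81.0  # mm, array to sample plane
    centering: str = "on_led"  # one LED on the optical axis, or "between_leds"

    def __post_init__(self) -> None:
        if self.pitch <= 0 or self.height <= 0:
            raise ValueError("pitch and height must be positive")
        if self.centering not in ("on_led", "between_leds"):
            raise ValueError(f"unknown centering {self.centering!r}")

    def grid_positions(self) -> np.ndarray:
        """All LED (x, y) positions in mm, sample-plane-centred coordinates."""
        if self.centering == "on_led":
            ix = np.arange(self.n_cols) - (self.n_cols - 1) // 2
            iy = np.arange(self.n_rows) - (self.n_rows - 1) // 2
        else:
            ix = np.arange(self.n_cols) - (self.n_cols - 1) / 2.0
            iy = np.arange(self.n_rows) - (self.n_rows - 1) / 2.0
        X, Y = np.meshgrid(ix * self.pitch, iy * self.pitch)
        return np.column_stack([X.ravel(), Y.ravel()])


@dataclass
class LEDPlan:
    """Ordered illumination plan: one entry per LED, sorted by radial distance.

    ``k_illum`` holds the illumination spatial frequencies ``sin(theta)/lambda``
    in cycles/μm; ``exposure_scale`` is the per-LED exposure ratio ``T_n/T_BF``
    (1 for brightfield LEDs, growing with the square of the radial distance in
    the darkfield).
    """

    positions: np.ndarray  # (n, 2) mm
    k_illum: np.ndarray  # (n, 2) cycles/μm
    radial_dist: np.ndarray  # (n,) mm
    is_brightfield: np.ndarray  # (n,) bool
    exposure_scale: np.ndarray  # (n,) dimensionless
    height: float  # mm
    wavelength: float  # nm

    def __post_init__(self) -> None:
        n = len(self.positions)
        for name in ("k_illum", "radial_dist", "is_brightfield", "exposure_scale"):
            if len(getattr(self, name)) != n:
                raise ValueError("LEDPlan field lengths disagree")
        if n and np.any(np.diff(self.radial_dist) < -1e-9):
            raise ValueError("LEDPlan must be ordered by increasing radial distance")

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def sin_theta(self) -> np.ndarray:
        return np.hypot(*self.k_illum.T) * (self.wavelength * 1e-3)

    @property
    def sin_theta_max(self) -> float:
        return float(self.sin_theta.max()) if len(self) else 0.0


@dataclass
class Pupil:
    """Complex pupil function sampled on a Fourier grid (cycles/μm)."""

    grid: np.ndarray  # complex, fftshift-free (DC at [0, 0])
    cutoff: float  # cycles/μm, = na_obj / lambda
    fx: np.ndarray  # 1-D frequency axes (cycles/μm)
    fy: np.ndarray
    defocus: float = 0.0  # μm
    zernike_coeffs: dict = field(default_factory=dict)

    @property
    def aperture(self) -> np.ndarray:
        return np.abs(self.grid) > 0


def effective_magnification(sys: OpticalSystem) -> float:
    """Magnification of the objective/tube-lens pair, ``M * f_tube / f_ref``."""
    return sys.mag_nominal * sys.f_tube / sys.f_reference


def depth_of_field(sys: OpticalSystem, wavelength: float | None = None) -> float:
    """Diffraction depth of field ``lambda / NA^2`` in μm.

    Low-NA objectives trade resolution for a large DOF; at NA 0.16 and
    530 nm this is ~20 μm, which is what makes post-capture digital
    refocusing over a useful axial range possible.
    """
    lam_um = (wavelength or sys.wavelength_green) * 1e-3
    return lam_um / sys.na_obj**2


def field_of_view(sys: OpticalSystem) -> tuple[float, float]:
    """Sensor extent referred to the sample plane, (x, y) in mm."""
    mag = effective_magnification(sys)
    h_px, w_px = sys.sensor_shape
    return (
        w_px * sys.pixel_pitch_camera * 1e-3 / mag,
        h_px * sys.pixel_pitch_camera * 1e-3 / mag,
    )


def _illum_na(d: np.ndarray, height: float) -> np.ndarray:
    return d / np.hypot(d, height)


def build_led_plan(
    arr: LEDArray,
    sys: OpticalSystem,
    *,
    n_leds: int | None = None,
    max_illum_na: float | None = None,
    wavelength: float | None = None,
) -> LEDPlan:
    """Select the LEDs nearest the optical axis and derive the illumination plan.

    Exactly one of ``n_leds`` / ``max_illum_na`` selects the circle of LEDs.
    LEDs at exactly equal radius are either all included or all excluded, so a
    count criterion may be unattainable exactly; the nearest attainable count
    is used with a warning.
    """
    if (n_leds is None) == (max_illum_na is None):
        raise ValueError("give exactly one of n_leds or max_illum_na")
    wavelength = wavelength or sys.wavelength_green

    pos = arr.grid_positions()
    d = np.hypot(pos[:, 0], pos[:, 1])
    order = np.lexsort((np.arctan2(pos[:, 1], pos[:, 0]), d))
    pos, d = pos[order], d[order]

    if max_illum_na is not None:
        if max_illum_na <= 0 or max_illum_na >= 1:
            raise ValueError("max_illum_na must be in (0, 1)")
        keep = _illum_na(d, arr.height) <= max_illum_na
        if not keep.any():
            raise ValueError("no LED satisfies the NA criterion")
        n_sel = int(keep.sum())
    else:
        if not 1 <= n_leds <= len(d):
            raise ValueError(f"n_leds must be in [1, {len(d)}], got {n_leds}")
        r_thresh = d[n_leds - 1]
        n_sel = int((d <= r_thresh + 1e-9).sum())
        if n_sel != n_leds:
            warnings.warn(
                f"ties at radius {r_thresh:.3f} mm: selecting {n_sel} LEDs "
                f"instead of the requested {n_leds}",
                stacklevel=2,
            )
    pos, d = pos[:n_sel], d[:n_sel]

    lam_um = wavelength * 1e-3
    sin_theta = pos / np.hypot(d, arr.height)[:, None]  # (sinθx, sinθy)
    k_illum = sin_theta / lam_um
    bf = _illum_na(d, arr.height) <= sys.na_obj

    # darkfield exposure grows as (d_n / d_bf_edge)^2; brightfield stays at T_BF
    d_edge_bf = arr.height * sys.na_obj / np.sqrt(1.0 - sys.na_obj**2)
    scale = np.maximum(1.0, (d / d_edge_bf) ** 2)
    scale[bf] = 1.0

    return LEDPlan(
        positions=pos,
        k_illum=k_illum,
        radial_dist=d,
        is_brightfield=bf,
        exposure_scale=scale,
        height=arr.height,
        wavelength=wavelength,
    )


def synthetic_na(sys: OpticalSystem, plan: LEDPlan) -> float:
    """``NA_syn = NA_obj + sin(theta_max)`` — the reconstruction band limit.

    The corresponding cutoff frequency is ``NA_syn / lambda`` cycles/μm.
    """
    if len(plan) == 0:
        raise ValueError("empty LED plan")
    return sys.na_obj + plan.sin_theta_max


def zernike_phase(fy: np.ndarray, fx: np.ndarray, cutoff: float, coeffs: dict) -> np.ndarray:
    """Sum of low-order Zernike aberration phases (radians) on the pupil grid.

    ``coeffs`` maps ``(n, m)`` indices to coefficients in radians on the unit
    pupil; supported: defocus (2,0), astigmatism (2,±2), coma (3,±1),
    spherical (4,0).
    """
    FX, FY = np.meshgrid(fx, fy)
    rho = np.hypot(FX, FY) / cutoff
    phi = np.arctan2(FY, FX)
    out = np.zeros_like(rho)
    for (n, m), c in coeffs.items():
        if (n, m) == (2, 0):
            z = 2 * rho**2 - 1
        elif (n, m) == (2, 2):
            z = rho**2 * np.cos(2 * phi)
        elif (n, m) == (2, -2):
            z = rho**2 * np.sin(2 * phi)
        elif (n, m) == (3, 1):
            z = (3 * rho**3 - 2 * rho) * np.cos(phi)
        elif (n, m) == (3, -1):
            z = (3 * rho**3 - 2 * rho) * np.sin(phi)
        elif (n, m) == (4, 0):
            z = 6 * rho**4 - 6 * rho**2 + 1
        else:
            raise ValueError(f"unsupported Zernike index {(n, m)}")
        out += c * z
    return out


def make_pupil(
    sys: OpticalSystem,
    wavelength: float,
    grid_shape: tuple[int, int],
    pixel_size: float,
    defocus: float = 0.0,
    zernike: dict | None = None,
) -> Pupil:
    """Circular pupil of radius ``NA_obj/lambda`` on an fft-ordered grid.

    ``pixel_size`` is the real-space sampling (μm) of the grid the pupil acts
    on. Defocus by ``z`` μm multiplies the aperture by the angular-spectrum
    factor ``exp(i 2π/λ z sqrt(1 − λ²k²))``.
    """
    lam_um = wavelength * 1e-3
    cutoff = sys.na_obj / lam_um
    ny, nx = grid_shape
    fy = np.fft.fftfreq(ny, d=pixel_size)
    fx = np.fft.fftfreq(nx, d=pixel_size)
    nyquist = 0.5 / pixel_size
    if cutoff > nyquist:
        raise ValueError(
            f"pupil cutoff {cutoff:.3f} cycles/μm exceeds grid Nyquist "
            f"{nyquist:.3f}; decrease pixel_size below {sys.na_obj and lam_um / (2 * sys.na_obj):.3f} μm"
        )
    FX, FY = np.meshgrid(fx, fy)
    k2 = FX**2 + FY**2
    aperture = k2 <= cutoff**2 + 1e-12
    grid = aperture.astype(np.complex128)
    if defocus != 0.0:
        kz = np.sqrt(np.maximum(0.0, 1.0 - lam_um**2 * k2))
        grid *= np.exp(1j * 2 * np.pi / lam_um * defocus * kz)
    zernike = dict(zernike or {})
    if zernike:
        grid *= np.exp(1j * zernike_phase(fy, fx, cutoff, zernike))
    grid[~aperture] = 0.0
    return Pupil(grid=grid, cutoff=cutoff, fx=fx, fy=fy, defocus=defocus, zernike_coeffs=zernike)


def exposure_schedule(plan: LEDPlan, t_bf: float) -> np.ndarray:
    """Per-LED exposure times in ms: ``T_n = T_BF * exposure_scale``.

    Darkfield frames collect far less scattered light, so their exposure is
    stretched in proportion to the squared LED distance from the axis; the
    recorded intensities are later divided back down by the same factor.
    """
    if t_bf <= 0:
        raise ValueError("t_bf must be positive")
    return t_bf * plan.exposure_scale


def rescale_intensity(frames: np.ndarray, plan: LEDPlan) -> np.ndarray:
    """Undo exposure scaling: ``I_n = I_raw * T_BF / T_n``."""
    frames = np.asarray(frames, dtype=np.float64)
    if len(frames) != len(plan):
        raise ValueError("frame count does not match plan")
    return frames / plan.exposure_scale[:, None, None]
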