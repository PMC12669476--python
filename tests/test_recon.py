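import warnings

import numpy as np
import pytest

from vsfpm import forward, optics, phantom, recon
from vsfpm.evalmetrics import pcc
from vsfpm.forward import NoiseParams, capture_stack
from vsfpm.recon import (
    ComplexField,
    ReconConfig,
    align_global_phase,
    amplitude_match,
    bandlimit,
    digital_refocus,
    fourier_upsample,
    gauss_newton_reconstruct,
    nrmse,
    phase_flatten,
    stitch,
    undistort,
)

from conftest import FieldObject


class TestGaussNewton:
    def test_inverse_crime_recovery(self, small_setup, plan177, bandlimited_phantom,
                                    noiseless_stack):
        obj, na_syn = bandlimited_phantom
        cfg = ReconConfig(n_iters=15, upsample=3)
        fld, _ = gauss_newton_reconstruct(noiseless_stack, small_setup["pupil"], cfg)
        cut = na_syn / (plan177.wavelength * 1e-3)
        z = align_global_phase(fld.field, obj.field)
        err = nrmse(bandlimit(z, fld.pixel_size, cut), obj.field)
        assert err < 0.01
        assert fld.na_limit == pytest.approx(na_syn, abs=1e-6)

    def test_misfit_non_increasing_noiseless(self, small_setup, noiseless_stack):
        cfg = ReconConfig(n_iters=8)
        fld, _ = gauss_newton_reconstruct(noiseless_stack, small_setup["pupil"], cfg)
        misfit = fld.provenance["misfit_per_epoch"]
        assert all(b <= a * (1 + 1e-9) for a, b in zip(misfit, misfit[1:]))

    def test_uniform_object_reconstructs_flat(self, plan177, small_setup):
        stack = capture_stack(FieldObject(np.ones((150, 150), complex), 0.3),
                              plan177, small_setup["pupil"],
                              noise_params=NoiseParams.none(), seed=0)
        fld, _ = gauss_newton_reconstruct(stack, small_setup["pupil"],
                                          ReconConfig(n_iters=5))
        assert fld.phase.std() < 1e-3

    def test_mismatched_frame_count_rejected(self, plan177, small_setup, noiseless_stack):
        import dataclasses
        with pytest.raises(ValueError, match="frame count"):
            dataclasses.replace(noiseless_stack,
                                frames=noiseless_stack.frames[:50].copy())

    def test_pupil_recovery_astigmatism(self, system, plan177, bandlimited_phantom):
        obj, _ = bandlimited_phantom
        lam = plan177.wavelength
        pup_true = optics.make_pupil(system, lam, (50, 50), 0.9, zernike={(2, 2): 0.5})
        pup_flat = optics.make_pupil(system, lam, (50, 50), 0.9)
        stack = capture_stack(obj, plan177, pup_true, 3,
                              noise_params=NoiseParams.none(), seed=0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, pup_rec = gauss_newton_reconstruct(
                stack, pup_flat, ReconConfig(n_iters=25, pupil_recovery=True))
        ap = pup_true.aperture
        r = pcc(np.angle(pup_rec.grid[ap]), np.angle(pup_true.grid[ap]))
        assert r > 0.9


class TestDigitalRefocus:
    def _field(self, seed=0):
        rng = np.random.default_rng(seed)
        z = rng.standard_normal((64, 64)) + 1j * rng.standard_normal((64, 64))
        z = bandlimit(z, 0.3, 1.0)
        return ComplexField.from_complex(z, 0.3, 0.7, 530.0)

    def test_zero_is_identity(self):
        f = self._field()
        out = digital_refocus(f, 0.0)
        assert np.allclose(out.field, f.field, atol=1e-12)

    def test_additivity(self):
        f = self._field()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = digital_refocus(digital_refocus(f, 1.3), 0.9)
            b = digital_refocus(f, 2.2)
        assert np.abs(a.field - b.field).max() < 1e-10

    def test_inverse(self):
        f = self._field()
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            out = digital_refocus(digital_refocus(f, 4.0), -4.0)
        assert np.abs(out.field - f.field).max() < 1e-10

    def test_defocused_capture_refocuses_to_in_focus_recon(
            self, system, plan177, small_setup, bandlimited_phantom, noiseless_stack):
        obj, na_syn = bandlimited_phantom
        base = ComplexField.from_complex(obj.field, obj.pixel_size, na_syn,
                                         plan177.wavelength)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            defoc = digital_refocus(base, 10.0)
        stack_z = capture_stack(FieldObject(defoc.field, obj.pixel_size), plan177,
                                small_setup["pupil"],
                                noise_params=NoiseParams.none(), seed=0)
        cfg = ReconConfig(n_iters=15)
        fld_z, _ = gauss_newton_reconstruct(stack_z, small_setup["pupil"], cfg)
        fld_0, _ = gauss_newton_reconstruct(noiseless_stack, small_setup["pupil"], cfg)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            back = digital_refocus(fld_z, -10.0)
        cut = na_syn / (plan177.wavelength * 1e-3)
        a = bandlimit(back.field, fld_0.pixel_size, cut)
        b = bandlimit(fld_0.field, fld_0.pixel_size, cut)
        assert nrmse(align_global_phase(a, b), b) < 0.05


class TestPhaseFlatten:
    def test_constant_patch_flagged(self):
        out, ok = phase_flatten(np.full((64, 64), 2.0))
        assert not ok
        assert np.all(out == 0)

    def test_linear_ramp_removed(self):
        ramp = np.outer(np.linspace(0, 1, 128), np.ones(128)) * 3.0
        out, ok = phase_flatten(ramp)
        assert ok
        interior = out[20:-20, 20:-20]
        # the normalised ramp has unit std; residual should be a few percent
        assert np.abs(interior).max() < 0.05 * np.ptp((ramp - ramp.mean()) / ramp.std())

    def test_output_mean_near_zero(self, phantom256):
        out, _ = phase_flatten(phantom256.phase)
        assert abs(out.mean()) < 1e-6 * max(out.std(), 1e-12)


class TestAmplitudeMatch:
    def test_identical_histograms_near_identity(self):
        rng = np.random.default_rng(0)
        x = rng.random((128, 128))
        out = amplitude_match(x, x.copy())
        assert np.abs(out - x).max() < 2 / 256 * np.ptp(x) + 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        x, ref = rng.random((64, 64)), rng.beta(2, 5, (64, 64))
        once = amplitude_match(x, ref)
        twice = amplitude_match(once, ref)
        assert np.abs(twice - once).max() < 2 / 256 * np.ptp(ref) + 1e-9

    def test_cdf_sup_distance(self):
        rng = np.random.default_rng(2)
        x, ref = rng.random((128, 128)), rng.beta(2, 5, (128, 128))
        out = amplitude_match(x, ref)
        qs = np.linspace(0.01, 0.99, 99)
        q_out = np.quantile(out, qs)
        q_ref = np.quantile(ref, qs)
        cdf_ref = np.searchsorted(np.sort(ref.ravel()), q_out) / ref.size
        assert np.abs(cdf_ref - qs).max() < 2 / 256 + 0.01


class TestStitch:
    def test_single_patch_identity(self):
        p = np.random.default_rng(0).random((32, 32))
        assert np.array_equal(stitch([p], [(0, 0)]), p)

    def test_shuffled_overlapping_grid_round_trip(self):
        rng = np.random.default_rng(3)
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(rng.standard_normal((200, 200)), 2)
        patches, offs = [], []
        for i in range(3):
            for j in range(3):
                y, x = i * 70, j * 70
                y, x = min(y, 200 - 80), min(x, 200 - 80)
                patches.append(img[y:y + 80, x:x + 80])
                offs.append((y, x))
        order = rng.permutation(9)
        out = stitch([patches[k] for k in order], [offs[k] for k in order])
        assert out.shape == img.shape
        assert nrmse(out, img) < 1e-3

    def test_constant_patches_conserve_value(self):
        patches = [np.full((40, 40), 5.0)] * 4
        offs = [(0, 0), (0, 30), (30, 0), (30, 30)]
        out = stitch(patches, offs)
        assert np.allclose(out, 5.0)

    def test_refinement_without_overlap_errors(self):
        p = np.random.default_rng(0).random((16, 16))
        with pytest.raises(ValueError):
            stitch([p, p], [(0, 0), (100, 100)], refine_px=2)


class TestUndistort:
    def test_zero_coefficients_identity(self, phantom256):
        out = undistort(phantom256.phase)
        assert np.array_equal(out, phantom256.phase)

    def test_distort_then_undistort_grid_target(self):
        # checkerboard-corner grid; measure residual corner displacement
        img = np.zeros((200, 200))
        img[::20, :] = 1.0
        img[:, ::20] = 1.0
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 1.0)
        params = {"k1": 0.08, "k2": 0.01}
        warped, p = phantom.misalign(img, distortion_params=params)
        fixed = undistort(warped, **p)
        interior = (slice(30, -30), slice(30, -30))
        # sub-pixel displacement estimate from the residual gradient
        gy, gx = np.gradient(img)
        denom = np.sum(gx[interior] ** 2 + gy[interior] ** 2)
        resid = fixed[interior] - img[interior]
        dx = np.sum(resid * gx[interior]) / denom
        dy = np.sum(resid * gy[interior]) / denom
        assert np.hypot(dx, dy) < 0.2
        assert np.abs(resid).mean() < 0.05 * np.ptp(img)

    def test_barrel_line_straightened(self):
        # single horizontal line off-centre, barrel distortion bows it
        img = np.zeros((160, 160))
        img[40, :] = 1.0
        from scipy.ndimage import gaussian_filter
        img = gaussian_filter(img, 1.5)
        params = {"k1": 0.1}
        warped, p = phantom.misalign(img, distortion_params=params)
        fixed = undistort(warped, **p)

        def curvature(im):
            cols = range(20, 140)
            ys = []
            for c in cols:
                col = im[:, c]
                if col.max() < 0.05:
                    continue
                ys.append(np.argmax(col) + (np.arange(len(col)) * col).sum() * 0)
            ys = np.array([np.sum(np.arange(im.shape[0]) * im[:, c]) / im[:, c].sum()
                           for c in cols])
            coef = np.polyfit(np.array(list(cols)), ys, 2)
            return abs(coef[0])

        assert curvature(warped) / max(curvature(fixed), 1e-12) > 10


class TestHelpers:
    def test_fourier_upsample_preserves_mean_and_samples(self):
        rng = np.random.default_rng(0)
        img = np.real(bandlimit(rng.standard_normal((40, 40)), 1.0, 0.15))
        up = fourier_upsample(img, 3)
        assert up.shape == (120, 120)
        assert up.mean() == pytest.approx(img.mean(), abs=1e-12)
        assert np.allclose(up[::3, ::3], img, atol=1e-10)

    def test_align_global_phase_removes_gauge(self):
        rng = np.random.default_rng(1)
        z = rng.standard_normal((16, 16)) + 1j * rng.standard_normal((16, 16))
        rotated = 0.7 * np.exp(1j * 1.2) * z
        assert nrmse(align_global_phase(rotated, z), z) < 1e-12
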