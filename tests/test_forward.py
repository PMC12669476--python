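import numpy as np
import pytest

from vsfpm import forward, optics, recon
from vsfpm.forward import NoiseParams, autofocus, autofocus_metric, brightfield_sum, capture_stack

from conftest import FieldObject


def _uniform_object(shape=(150, 150), px=0.3):
    return FieldObject(np.ones(shape, dtype=complex), px)


class TestCaptureStack:
    def test_uniform_object_on_axis_constant(self, plan177, small_setup):
        stack = capture_stack(_uniform_object(), plan177, small_setup["pupil"],
                              noise_params=NoiseParams.none(), seed=0)
        bf0 = stack.frames[0] / stack.gain
        assert np.allclose(bf0, bf0.flat[0], atol=1e-9)
        assert bf0.flat[0] == pytest.approx(1.0, abs=1e-9)

    def test_uniform_object_darkfield_black(self, plan177, small_setup):
        stack = capture_stack(_uniform_object(), plan177, small_setup["pupil"],
                              noise_params=NoiseParams.none(), seed=0)
        dark = ~plan177.is_brightfield
        assert np.abs(stack.frames[dark]).max() < 1e-9

    def test_bandlimited_object_on_axis_is_downsampled_intensity(self, system, plan177):
        # object spectrum inside na_obj/lambda: the on-axis frame is exactly
        # the ideally sampled |object|^2
        rng = np.random.default_rng(1)
        px, ds = 0.3, 3
        obj = 1.0 + 0.2 * rng.standard_normal((150, 150))
        cut = system.na_obj / (plan177.wavelength * 1e-3)
        obj = recon.bandlimit(obj, px, 0.9 * cut)
        pupil = optics.make_pupil(system, plan177.wavelength, (50, 50), px * ds)
        stack = capture_stack(FieldObject(obj, px), plan177, pupil,
                              downsample_factor=ds, noise_params=NoiseParams.none(), seed=0)
        expected = np.abs(obj[::ds, ::ds]) ** 2
        got = stack.frames[0] / stack.gain
        assert recon.nrmse(got, expected) < 1e-6

    def test_noiseless_capture_deterministic_and_linear_in_exposure(
            self, plan177, small_setup, bandlimited_phantom):
        obj, _ = bandlimited_phantom
        a = capture_stack(obj, plan177, small_setup["pupil"],
                          noise_params=NoiseParams.none(), gain=1000.0, seed=0)
        b = capture_stack(obj, plan177, small_setup["pupil"],
                          noise_params=NoiseParams.none(), gain=2000.0, seed=99)
        assert np.allclose(2 * a.frames, b.frames)

    def test_shot_noise_deterministic_given_seed(self, plan177, small_setup,
                                                 bandlimited_phantom):
        obj, _ = bandlimited_phantom
        a = capture_stack(obj, plan177, small_setup["pupil"], seed=5)
        b = capture_stack(obj, plan177, small_setup["pupil"], seed=5)
        c = capture_stack(obj, plan177, small_setup["pupil"], seed=6)
        assert np.array_equal(a.frames, b.frames)
        assert not np.array_equal(a.frames, c.frames)

    def test_energy_conservation_phase_only(self, system, plan177):
        # phase-only object band-limited inside the pupil: Parseval gives
        # total frame intensity = total illumination through the aperture
        px, ds = 0.3, 3
        rng = np.random.default_rng(2)
        cut = system.na_obj / (plan177.wavelength * 1e-3)
        phase = np.real(recon.bandlimit(0.1 * rng.standard_normal((150, 150)), px, 0.4 * cut))
        obj = np.exp(1j * phase)
        pupil = optics.make_pupil(system, plan177.wavelength, (50, 50), px * ds)
        stack = capture_stack(FieldObject(obj, px), plan177, pupil,
                              downsample_factor=ds, noise_params=NoiseParams.none(), seed=0)
        total = stack.frames[0].sum() / stack.gain
        assert total == pytest.approx(50 * 50, rel=1e-6)

    def test_conjugate_led_frames_related_for_real_object(self, system):
        # real object (Hermitian spectrum), symmetric real pupil: the fields
        # for +k and -k illumination are complex conjugates, so the recorded
        # intensity frames coincide
        rng = np.random.default_rng(3)
        px, ds, lam = 0.3, 3, 530.0
        obj = 1.0 + 0.3 * np.real(recon.bandlimit(rng.standard_normal((96, 96)), px, 0.5))
        k = 0.35  # cycles/um, darkfield-ish tilt
        plan = optics.LEDPlan(
            positions=np.array([[20.0, 8.0], [-20.0, -8.0]]),
            k_illum=np.array([[k, 0.4 * k], [-k, -0.4 * k]]),
            radial_dist=np.array([21.5, 21.5]),
            is_brightfield=np.array([False, False]),
            exposure_scale=np.array([1.0, 1.0]),
            height=81.0, wavelength=lam,
        )
        pupil = optics.make_pupil(system, lam, (32, 32), px * ds)
        stack = capture_stack(FieldObject(obj.astype(complex), px), plan, pupil,
                              downsample_factor=ds, noise_params=NoiseParams.none(), seed=0)
        assert recon.nrmse(stack.frames[0], stack.frames[1]) < 1e-9

    def test_undersampled_grid_rejected(self, system, plan177):
        px = 0.45  # > lambda/(2 NA_syn) ~ 0.38, but raw grid still holds the pupil
        pupil = optics.make_pupil(system, plan177.wavelength, (50, 50), px * 3)
        with pytest.raises(ValueError, match="pixel size"):
            capture_stack(FieldObject(np.ones((150, 150), complex), px),
                          plan177, pupil, noise_params=NoiseParams.none(), seed=0)

    def test_saturation_flagged(self, plan177, small_setup):
        np_ = NoiseParams(shot=False, read_sigma=0.0, full_well=100.0)
        stack = capture_stack(_uniform_object(), plan177, small_setup["pupil"],
                              gain=5000.0, noise_params=np_, seed=0)
        assert stack.saturated[0].all()


class TestBrightfieldSum:
    def test_single_frame_identity(self):
        f = np.random.default_rng(0).random((1, 8, 8))
        assert np.array_equal(brightfield_sum(f), f[0])

    def test_permutation_invariant(self, noiseless_stack):
        s1 = brightfield_sum(noiseless_stack)
        frames = noiseless_stack.rescaled()
        rng = np.random.default_rng(0)
        s2 = frames[rng.permutation(len(frames))].sum(axis=0)
        assert np.allclose(s1, s2)

    def test_uniform_object_sum_counts_brightfield_leds(self, plan177, small_setup):
        stack = capture_stack(_uniform_object(), plan177, small_setup["pupil"],
                              noise_params=NoiseParams.none(), seed=0)
        n_bf = int(plan177.is_brightfield.sum())
        total = brightfield_sum(stack) / stack.gain
        assert np.allclose(total, n_bf, rtol=1e-9)


class TestAutofocus:
    def test_constant_image_zero_score(self):
        assert autofocus_metric(np.full((1, 16, 16), 3.0)) == 0.0

    def test_score_scale_invariant(self):
        rng = np.random.default_rng(0)
        f = rng.random((3, 16, 16))
        assert autofocus_metric(f) == pytest.approx(autofocus_metric(7.3 * f))

    def test_zero_mean_image_rejected(self):
        with pytest.raises(ValueError):
            autofocus_metric(np.zeros((1, 8, 8)))

    def test_through_focus_series_finds_focus(self, system, plan177, small_setup,
                                              bandlimited_phantom):
        obj, _ = bandlimited_phantom
        ring = forward.darkfield_ring_indices(plan177)
        base = recon.ComplexField.from_complex(obj.field, obj.pixel_size, 0.7,
                                               plan177.wavelength)
        z_grid = np.arange(-9.0, 9.1, 3.0)
        groups = []
        import warnings
        for z in z_grid:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                defoc = recon.digital_refocus(base, z)
            stack = capture_stack(FieldObject(defoc.field, obj.pixel_size),
                                  plan177, small_setup["pupil"],
                                  noise_params=NoiseParams.none(), seed=0)
            groups.append(stack.frames[ring])
        z_star = autofocus(groups, z_grid)
        assert abs(z_star) <= 3.0  # within one z-step of true focus (z = 0)

    def test_darkfield_ring_is_darkfield(self, plan177):
        ring = forward.darkfield_ring_indices(plan177)
        assert len(ring) >= 4
        assert not plan177.is_brightfield[ring].any()
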