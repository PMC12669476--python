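import warnings

import numpy as np
import pytest

from vsfpm import phantom, register
from vsfpm.register import (
    RegistrationError,
    chromatic_align,
    corner_error,
    curate_pairs,
    histogram_match_color,
    mutual_information,
    register_perspective,
    white_balance,
)

H_TEST = np.array([[1.01, 0.01, 3.0], [-0.008, 0.995, -2.0], [1e-5, -6e-6, 1.0]])


class TestRegisterPerspective:
    def test_self_registration_identity(self, phantom256):
        H, _, n_in = register_perspective(phantom256.phase, phantom256.phase)
        assert corner_error(H, np.eye(3), phantom256.phase.shape) < 0.1
        assert n_in >= 8

    def test_known_homography_recovered(self, phantom256):
        warped, H_true = phantom.misalign(phantom256.phase, homography=H_TEST)
        H_est, _, _ = register_perspective(warped, phantom256.phase)
        # H_est maps warped -> original, i.e. the inverse of the truth
        assert corner_error(H_est, np.linalg.inv(H_true), warped.shape) < 0.5

    def test_cross_stain_model_registration(self, phantom256):
        st = phantom.render_hne(phantom256)
        warped, H_true = phantom.misalign(st.phase_stained, homography=H_TEST)
        H_est, _, _ = register_perspective(phantom256.phase, warped)
        assert corner_error(H_est, H_true, warped.shape) < 1.0

    def test_featureless_input_raises(self):
        flat = np.zeros((128, 128))
        with pytest.raises(RegistrationError):
            register_perspective(flat, flat)


class TestMutualInformation:
    def test_independent_noise_is_low(self):
        rng = np.random.default_rng(0)
        a = rng.random((256, 256))
        b = rng.random((256, 256))
        assert mutual_information(a, b, n_bins=64) < 0.1

    def test_identity_upper_bound(self, phantom256):
        a = phantom256.phase
        self_mi = mutual_information(a, a)
        assert self_mi >= mutual_information(a, phantom256.amplitude) - 1e-12
        # MI(a, a) equals the entropy of the binned image
        lo, hi = a.min(), a.max()
        hist, _ = np.histogram((a - lo) / (hi - lo), bins=64, range=(0, 1))
        p = hist / hist.sum()
        entropy = -np.sum(p[p > 0] * np.log2(p[p > 0]))
        assert self_mi == pytest.approx(entropy, abs=1e-9)

    def test_monotone_remap_invariance(self, phantom256):
        a = phantom256.phase
        b = phantom256.amplitude
        remapped = np.exp(2.0 * b)  # strictly monotone
        mi1 = mutual_information(a, b)
        mi2 = mutual_information(a, remapped)
        assert mi1 == pytest.approx(mi2, abs=0.12)  # binning error only

    def test_constant_image_flagged_zero(self):
        with pytest.warns(UserWarning, match="constant"):
            assert mutual_information(np.zeros((32, 32)), np.ones((32, 32))) == 0.0


class TestCuratePairs:
    def test_registered_phantom_mostly_accepted(self, phantom256):
        st = phantom.render_hne(phantom256)
        pairs = curate_pairs(phantom256.phase, st.phase_stained, st.rgb, patch_size=64)
        tissue_pairs = [p for p in pairs
                        if phantom256.tissue_mask[p.coords[0]:p.coords[0] + 64,
                                                  p.coords[1]:p.coords[1] + 64].mean() > 0.5]
        frac = np.mean([p.accepted for p in tissue_pairs])
        assert frac >= 0.9

    def test_background_patches_rejected(self):
        # pure background: constant phase before and after staining
        pu = np.zeros((128, 128))
        ps = np.zeros((128, 128))
        rgb = np.ones((128, 128, 3))
        pairs = curate_pairs(pu, ps, rgb, patch_size=64)
        assert not any(p.accepted for p in pairs)

    def test_zero_cutoff_accepts_all(self, phantom256):
        st = phantom.render_hne(phantom256)
        pairs = curate_pairs(phantom256.phase, st.phase_stained, st.rgb,
                             patch_size=64, mi_cutoff=0.0)
        assert all(p.accepted for p in pairs)

    def test_acceptance_monotone_in_cutoff(self, phantom256):
        st = phantom.render_hne(phantom256)
        counts = []
        for cutoff in (0.0, 0.2, 0.4, 0.8, 1.5):
            pairs = curate_pairs(phantom256.phase, st.phase_stained, st.rgb,
                                 patch_size=64, mi_cutoff=cutoff)
            counts.append(sum(p.accepted for p in pairs))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_accepted_flag_consistent_with_score(self, phantom256):
        st = phantom.render_hne(phantom256)
        for p in curate_pairs(phantom256.phase, st.phase_stained, st.rgb, patch_size=64):
            assert p.accepted == (p.mi_score >= register.DEFAULT_MI_CUTOFF)


class TestChromaticAlign:
    def test_identical_channels_identity(self, phantom256):
        g = phantom256.amplitude
        rgb, tfs = chromatic_align(g, g, g)
        for name in ("r", "b"):
            assert corner_error(tfs[name], np.eye(3), g.shape) < 0.1

    def test_known_channel_offset_recovered(self, phantom256):
        g = phantom.render_hne(phantom256).rgb[..., 1]
        shift = np.array([[1, 0, 2.0], [0, 1, -1.5], [0, 0, 1]], float)
        r, _ = phantom.misalign(g, homography=shift)
        rgb, tfs = chromatic_align(r, g, g.copy())
        # recovered transform should undo the shift: translation (-2.0, 1.5)
        assert tfs["r"][0, 2] == pytest.approx(-2.0, abs=0.2)
        assert tfs["r"][1, 2] == pytest.approx(1.5, abs=0.2)

    def test_chromatic_scale_recovered(self, phantom256):
        g = phantom.render_hne(phantom256).rgb[..., 1]
        s = 1.002
        c = (g.shape[1] - 1) / 2
        H = np.array([[s, 0, c * (1 - s)], [0, s, c * (1 - s)], [0, 0, 1]])
        b, _ = phantom.misalign(g, homography=H)
        _, tfs = chromatic_align(g.copy(), g, b, mode="similarity")
        est_scale = np.sqrt(abs(np.linalg.det(tfs["b"][:2, :2])))
        assert est_scale == pytest.approx(1 / s, abs=1e-3)

    def test_featureless_channel_warns_identity(self):
        g = np.random.default_rng(0).random((96, 96))
        flat = np.zeros((96, 96))
        with pytest.warns(UserWarning, match="chromatic"):
            _, tfs = chromatic_align(flat, g, g.copy())
        assert np.allclose(tfs["r"], np.eye(3))


class TestWhiteBalance:
    def test_white_roi_identity(self):
        rgb = np.random.default_rng(0).random((64, 64, 3)) * 0.8
        rgb[:8, :8] = 1.0
        out = white_balance(rgb, (slice(0, 8), slice(0, 8)))
        assert np.allclose(out, np.clip(rgb, 0, 1))

    def test_color_cast_removed(self):
        cast = np.array([0.9, 0.8, 0.7])
        rgb = np.ones((32, 32, 3)) * cast
        out = white_balance(rgb, (slice(0, 8), slice(0, 8)))
        assert np.allclose(out, 1.0)

    def test_idempotent_with_uniform_background_roi(self):
        rgb = np.random.default_rng(1).random((32, 32, 3))
        rgb[:8, :8] = np.array([0.9, 0.8, 0.7])  # uniform background cast
        roi = (slice(0, 8), slice(0, 8))
        once = white_balance(rgb, roi)
        assert np.allclose(white_balance(once, roi), once, atol=1e-9)

    def test_zero_channel_rejected(self):
        rgb = np.zeros((16, 16, 3))
        with pytest.raises(ValueError):
            white_balance(rgb, (slice(0, 4), slice(0, 4)))


class TestHistogramMatchColor:
    def test_identity_reference(self):
        rgb = np.random.default_rng(0).random((64, 64, 3))
        out = histogram_match_color(rgb, rgb.copy())
        assert np.abs(out - rgb).max() < 2 / 256 + 1e-9

    def test_idempotent(self):
        rng = np.random.default_rng(1)
        src, ref = rng.random((64, 64, 3)), rng.beta(2, 4, (64, 64, 3))
        once = histogram_match_color(src, ref)
        twice = histogram_match_color(once, ref)
        assert np.abs(twice - once).max() < 2 / 256 + 1e-9
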