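"""Dose-comparison operators: oracles, identities, invariants."""

from __future__ import annotations

import numpy as np
import pytest
from scipy import ndimage
from scipy.special import erf

from doseqa.compare import (
    GAMMA_CRITERIA,
    ComparisonImage,
    GammaCriteria,
    Method,
    compare,
    dd_map,
    dta_map,
    gamma_map,
    gamma_map_bruteforce,
    gradient_map,
    n_channels,
    ratio_map,
    ssim_map,
    SsimParams,
)
from doseqa.plans import DoseImage

from conftest import smooth_field


def edge_field(n=48, sigma_mm=1.5, pitch=0.8, amplitude=100.0) -> DoseImage:
    """A single steep erf edge, constant along rows."""
    x = (np.arange(n) - n / 2) * pitch
    profile = amplitude * 0.5 * (1 + erf(x / (sigma_mm * np.sqrt(2))))
    return DoseImage(np.tile(profile, (n, 1)), (pitch, pitch))


class TestGamma:
    def test_identical_images_give_zero(self, rendered_pair):
        ref, _ = rendered_pair
        g = gamma_map(ref, ref, GammaCriteria(3.0, 3.0))
        assert np.all(g.channels == 0.0)

    @pytest.mark.parametrize("dd,dta", [(3.0, 1.0), (1.0, 3.0), (2.0, 2.0)])
    def test_matches_bruteforce_oracle_on_random_fields(self, rng, dd, dta):
        for _ in range(12):
            ref = smooth_field(rng, (12, 12))
            ev = smooth_field(rng, (12, 12))
            crit = GammaCriteria(dd, dta, subsample_factor=1)
            fast = gamma_map(ref, ev, crit).channels[0]
            oracle = gamma_map_bruteforce(ref, ev, crit)
            np.testing.assert_allclose(fast, oracle, atol=1e-9)

    def test_one_pixel_shift_bounded_by_pure_dta_gamma(self):
        """A 0.8 mm translation can always be 'repaired' spatially, so
        |gamma| <= shift/dta in the interior."""
        ref = edge_field()
        ev = DoseImage(np.roll(ref.pixels, 1, axis=1), ref.pixel_pitch_mm)
        interior = (slice(None), slice(4, -4))
        g31 = gamma_map(ref, ev, GammaCriteria(3.0, 1.0, subsample_factor=1)).channels[0]
        assert np.all(np.abs(g31[interior]) <= 0.8 + 1e-9)
        g13 = gamma_map(ref, ev, GammaCriteria(1.0, 3.0, subsample_factor=4)).channels[0]
        assert np.all(np.abs(g13[interior]) <= 0.8 / 3.0 + 1e-9)

    def test_loosening_criteria_never_increases_gamma(self, rng):
        ref = smooth_field(rng, (16, 16))
        ev = smooth_field(rng, (16, 16))
        tight = np.abs(gamma_map(ref, ev, GammaCriteria(2.0, 2.0)).channels[0])
        loose_dd = np.abs(gamma_map(ref, ev, GammaCriteria(4.0, 2.0)).channels[0])
        loose_dta = np.abs(gamma_map(ref, ev, GammaCriteria(2.0, 4.0)).channels[0])
        assert np.all(loose_dd <= tight + 1e-12)
        assert np.all(loose_dta <= tight + 1e-12)

    def test_bounded_by_pure_dose_difference_gamma(self, rng):
        ref = smooth_field(rng, (16, 16))
        ev = smooth_field(rng, (16, 16))
        crit = GammaCriteria(3.0, 2.0)
        g = np.abs(gamma_map(ref, ev, crit).channels[0])
        pure_dd = np.abs(ev.pixels - ref.pixels) / (0.03 * ref.max())
        assert np.all(g <= pure_dd + 1e-12)

    def test_sign_follows_local_dose_difference(self, rng):
        ref = smooth_field(rng, (16, 16))
        ev = DoseImage(ref.pixels * 1.05)
        g = gamma_map(ref, ev, GammaCriteria(3.0, 3.0)).channels[0]
        assert np.all(g[ref.pixels > 0] >= 0.0)

    def test_zero_reference_rejected(self):
        z = np.zeros((8, 8))
        with pytest.raises(ValueError):
            gamma_map(DoseImage(z), DoseImage(z), GammaCriteria(3.0, 3.0))


class TestRatio:
    def test_identity_gives_ones(self, rendered_pair):
        ref, _ = rendered_pair
        assert np.all(ratio_map(ref, ref).channels == 1.0)

    def test_doubled_dose_gives_twos_in_field(self, rng):
        ref = smooth_field(rng)
        r = ratio_map(ref, DoseImage(2.0 * ref.pixels)).channels[0]
        np.testing.assert_allclose(r, 2.0)

    def test_zero_border_falls_back_to_neutral_one(self):
        pix = np.zeros((10, 10))
        pix[3:7, 3:7] = 50.0
        ref = DoseImage(pix)
        ev = DoseImage(pix * 1.5)
        r = ratio_map(ref, ev).channels[0]
        assert np.all(r[0, :] == 1.0)
        np.testing.assert_allclose(r[3:7, 3:7], 1.5)


class TestDoseDifference:
    def test_identity_gives_zeros(self, rendered_pair):
        ref, _ = rendered_pair
        assert np.all(dd_map(ref, ref, relative=True).channels == 0.0)
        assert np.all(dd_map(ref, ref, relative=False).channels == 0.0)

    def test_uniform_offset_gives_constant_relative_map(self, rng):
        ref = smooth_field(rng)
        ev = DoseImage(ref.pixels + 0.03 * ref.max())
        np.testing.assert_allclose(dd_map(ref, ev, relative=True).channels[0], 0.03)

    def test_swap_identity_on_random_fields(self, rng):
        ref = smooth_field(rng)
        ev = smooth_field(rng)
        fwd = dd_map(ref, ev, relative=True).channels[0]
        rev = dd_map(ev, ref, relative=True).channels[0]
        np.testing.assert_allclose(fwd, -rev * ev.max() / ref.max(), rtol=1e-12)

    def test_absolute_is_plain_difference(self, rng):
        ref = smooth_field(rng)
        ev = smooth_field(rng)
        np.testing.assert_array_equal(
            dd_map(ref, ev, relative=False).channels[0], ev.pixels - ref.pixels
        )


class TestDta:
    def test_identity_gives_zero_both_channels(self, rendered_pair):
        ref, _ = rendered_pair
        assert np.all(dta_map(ref, ref).channels == 0.0)

    def test_translation_recovered_in_penumbra(self):
        """+2 px (1.6 mm) x-translation of a monotone edge: dta_x ~ +1.6 mm
        where the dose actually differs, i.e. in the penumbra."""
        ref = edge_field(n=64, sigma_mm=3.0)
        ev = DoseImage(np.roll(ref.pixels, 2, axis=1), ref.pixel_pitch_mm)
        d = dta_map(ref, ev)
        profile = ref.pixels[0]
        penumbra = (profile > 0.1 * profile.max()) & (profile < 0.9 * profile.max())
        penumbra[:8] = penumbra[-8:] = False
        assert abs(np.median(d.channels[0][:, penumbra]) - 1.6) < 0.1
        # the shift is towards +x, so the recovered distances are too
        assert np.all(d.channels[0][:, penumbra] > 0.0)

    def test_no_crossing_saturates_at_window_bound(self):
        ref = DoseImage(np.full((20, 20), 50.0))
        ev = DoseImage(np.full((20, 20), 60.0))
        d = dta_map(ref, ev)
        W = 20 * 0.8 / 2.0
        assert np.all(np.abs(d.channels) == W)

    def test_channels_are_named_x_then_y(self, rendered_pair):
        ref, ev = rendered_pair
        d = dta_map(ref, ev)
        assert d.channel_names == ["dta_x", "dta_y"]


class TestSsim:
    def test_identity_gives_ones(self, rendered_pair):
        ref, _ = rendered_pair
        s = ssim_map(ref, ref).channels[0]
        np.testing.assert_allclose(s, 1.0, atol=1e-12)

    def test_constant_images_reduce_to_luminance_term(self):
        mu_x, mu_y, L = 30.0, 50.0, 100.0
        ref = DoseImage(np.full((9, 9), mu_x))
        ev = DoseImage(np.full((9, 9), mu_y))
        s = ssim_map(ref, ev, SsimParams(window_side_px=5, dynamic_range=L)).channels[0]
        c1 = (0.01 * L) ** 2
        expected = (2 * mu_x * mu_y + c1) / (mu_x**2 + mu_y**2 + c1)
        np.testing.assert_allclose(s, expected, rtol=1e-12)

    def test_affine_rescale_keeps_ssim_below_one(self, rng):
        ref = smooth_field(rng, (32, 32))
        ev = DoseImage(1.3 * ref.pixels + 5.0)
        s = ssim_map(ref, ev).channels[0]
        assert np.all(s <= 1.0 + 1e-9)
        assert s.mean() < 0.999

    def test_bounded_in_minus_one_one(self, rng):
        for _ in range(5):
            ref = smooth_field(rng, (24, 24))
            ev = smooth_field(rng, (24, 24))
            s = ssim_map(ref, ev).channels[0]
            assert np.all(s <= 1.0 + 1e-9)
            assert np.all(s >= -1.0 - 1e-9)

    def test_matches_skimage_reference(self, rng):
        """Interior of the map agrees with scikit-image's SSIM."""
        from skimage.metrics import structural_similarity

        ref = smooth_field(rng, (40, 40))
        ev = smooth_field(rng, (40, 40))
        L = ref.max()
        ours = ssim_map(ref, ev, SsimParams(dynamic_range=L)).channels[0]
        _, theirs = structural_similarity(
            ref.pixels, ev.pixels, win_size=11, data_range=L,
            gaussian_weights=False, use_sample_covariance=False, full=True,
        )
        m = 6
        np.testing.assert_allclose(ours[m:-m, m:-m], theirs[m:-m, m:-m], atol=1e-9)

    def test_window_larger_than_image_rejected(self):
        small = DoseImage(np.ones((5, 5)))
        with pytest.raises(ValueError):
            ssim_map(small, small, SsimParams(window_side_px=11))


class TestGradient:
    def test_identity_gives_zero_magnitude_and_direction(self, rendered_pair):
        ref, _ = rendered_pair
        g = gradient_map(ref, ref)
        assert np.all(g.channels == 0.0)

    def test_linear_ramp_gives_sobel_response_8s(self):
        n, slope = 24, 0.004  # relative-DD slope per pixel
        R = np.full((n, n), 100.0)
        ramp = slope * 100.0 * np.arange(n)[None, :] * np.ones((n, 1))
        g = gradient_map(DoseImage(R), DoseImage(R + ramp))
        mag, direction = g.channels
        i = slice(2, -2)
        np.testing.assert_allclose(mag[i, i], 8.0 * slope, rtol=1e-9)
        np.testing.assert_allclose(direction[i, i], 0.0, atol=1e-12)

    def test_rotating_dd_map_rotates_direction_and_keeps_magnitude(self, rng):
        D = ndimage.uniform_filter(rng.uniform(-20, 20, (40, 40)), 5)
        R = np.full((40, 40), 100.0)
        g1 = gradient_map(DoseImage(R), DoseImage(R + D))
        g2 = gradient_map(DoseImage(R), DoseImage(np.rot90(R + D)))
        m1, d1 = g1.channels
        m2, d2 = g2.channels
        i = slice(3, -3)
        np.testing.assert_allclose(m2[i, i], np.rot90(m1)[i, i], atol=1e-12)
        # quarter-turn rotates the gradient direction by -pi/2 (y-down frame)
        delta = np.exp(1j * d2[i, i]) - np.exp(1j * (np.rot90(d1)[i, i] - np.pi / 2))
        assert np.abs(delta).max() < 1e-9


class TestDispatcher:
    def test_twelve_distinct_variants(self):
        assert len(list(Method)) == 12
        assert len(GAMMA_CRITERIA) == 5

    @pytest.mark.parametrize("method", list(Method))
    def test_identity_returns_neutral_map(self, rendered_pair, method):
        """Each method's self-comparison is its neutral value."""
        ref, _ = rendered_pair
        comp = compare(ref, ref, method)
        assert comp.n_channels == n_channels(method)
        neutral = 1.0 if method in (Method.RATIO, Method.SSIM) else 0.0
        np.testing.assert_allclose(comp.channels, neutral, atol=1e-9)

    def test_dd_dta_stacks_three_channels(self, rendered_pair):
        ref, ev = rendered_pair
        comp = compare(ref, ev, Method.DD_DTA)
        assert comp.channel_names == ["rel_dd", "dta_x", "dta_y"]
        np.testing.assert_array_equal(
            comp.channels[0], dd_map(ref, ev, relative=True).channels[0]
        )

    def test_unknown_method_rejected(self, rendered_pair):
        ref, ev = rendered_pair
        with pytest.raises(ValueError):
            compare(ref, ev, "gamma99")

    def test_mismatched_shapes_rejected(self, rng):
        a = smooth_field(rng, (10, 10))
        b = smooth_field(rng, (12, 12))
        with pytest.raises(ValueError, match="shape"):
            compare(a, b, Method.REL_DD)


class TestComparisonImage:
    def test_rejects_too_many_channels(self):
        with pytest.raises(ValueError):
            ComparisonImage(np.zeros((4, 5, 5)), Method.DTA, list("abcd"))

    def test_rejects_non_finite(self):
        bad = np.full((1, 4, 4), np.nan)
        with pytest.raises(ValueError):
            ComparisonImage(bad, Method.RATIO, ["ratio"])
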