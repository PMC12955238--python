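"""Exponential adaptation weighting, diagonal corrections, and the
local-vs-global color-difference time course."""

import numpy as np
import pytest

from gazediet import adaptation_analysis as ad
from gazediet.gaze_models import GazeTrace
from gazediet.retinal_sampling import RetinalSampler
from gazediet.spectral_core import ViewingConditions, daylight_spd


class TestExponentialWeights:
    def test_single_frame_gets_unit_weight(self):
        np.testing.assert_array_equal(ad.exponential_weights([3.0], 3.0, 1.0),
                                      [1.0])

    def test_one_second_gap_at_unit_tau_gives_ratio_e(self):
        w = ad.exponential_weights([0.0, 1.0], 1.0, 1.0)
        assert w[1] / w[0] == pytest.approx(np.e, rel=1e-12)
        assert w.sum() == pytest.approx(1.0)
        assert w[1] == w.max()  # most recent frame dominates

    def test_huge_tau_gives_uniform_weights(self):
        w = ad.exponential_weights(np.arange(100) * 0.02, 2.0, 1e9)
        np.testing.assert_allclose(w, 0.01, atol=1e-6)

    def test_empty_history_rejected(self):
        with pytest.raises(ValueError):
            ad.exponential_weights([], 0.0, 1.0)


class TestLocalAdaptationField:
    def test_constant_history_gives_reciprocal_gains(self):
        patch = np.full((5, 5, 3), 2.0)
        fld = ad.local_adaptation_field([(patch, 0.0), (patch, 0.02)], 0.02, 1.0)
        np.testing.assert_allclose(fld.gains, 0.5, rtol=1e-12)

    def test_single_frame_history(self):
        patch = np.linspace(1, 4, 75).reshape(5, 5, 3)
        fld = ad.local_adaptation_field([(patch, 0.0)], 0.0, 1.0)
        np.testing.assert_allclose(fld.gains, 1.0 / patch, rtol=1e-12)

    def test_two_frame_history_matches_hand_weighted_mean(self, rng):
        a = rng.uniform(0.5, 2.0, (4, 4, 3))
        b = rng.uniform(0.5, 2.0, (4, 4, 3))
        fld = ad.local_adaptation_field([(a, 0.0), (b, 1.0)], 1.0, 1.0)
        wa, wb = np.exp(-1.0), 1.0
        expected = (wa * a + wb * b) / (wa + wb)
        np.testing.assert_allclose(1.0 / fld.gains, expected, rtol=1e-12)

    def test_mismatched_grids_rejected(self):
        with pytest.raises(ValueError):
            ad.local_adaptation_field([(np.ones((4, 4, 3)), 0.0),
                                       (np.ones((5, 5, 3)), 0.02)], 0.02, 1.0)


class TestDiagonalCorrections:
    def test_frame_equal_to_adaptation_state_maps_to_unity(self, rng):
        frame = rng.uniform(0.5, 2.0, (6, 6, 3))
        fld = ad.local_adaptation_field([(frame, 0.0)], 0.0, 1.0)
        np.testing.assert_allclose(ad.diagonal_correct_local(frame, fld), 1.0,
                                   rtol=1e-9)

    def test_unit_gains_are_identity(self, rng):
        frame = rng.uniform(0.5, 2.0, (6, 6, 3))
        fld = ad.AdaptationField(np.ones((6, 6, 3)), 1.0)
        np.testing.assert_array_equal(ad.diagonal_correct_local(frame, fld),
                                      frame)

    def test_matches_elementwise_loop_oracle(self, rng):
        frame = rng.uniform(0.5, 2.0, (3, 3, 3))
        gains = rng.uniform(0.5, 2.0, (3, 3, 3))
        fld = ad.AdaptationField(gains, 1.0)
        got = ad.diagonal_correct_local(frame, fld)
        for i in range(3):
            for j in range(3):
                for c in range(3):
                    assert got[i, j, c] == frame[i, j, c] * gains[i, j, c]

    def test_global_correction_normalizes_the_spatial_mean(self, rng):
        img = rng.uniform(0.5, 2.0, (10, 12, 3))
        out = ad.diagonal_correct_global(img, ad.global_gains_of(img))
        np.testing.assert_allclose(out.reshape(-1, 3).mean(axis=0), 1.0,
                                   atol=1e-9)

    def test_uniform_image_corrects_to_unity(self):
        img = np.full((4, 4, 3), 3.0)
        out = ad.diagonal_correct_global(img, ad.global_gains_of(img))
        np.testing.assert_allclose(out, 1.0, rtol=1e-12)

    def test_diagonal_illuminant_is_exactly_discounted(self, rng):
        """If a relighting acts as one diagonal transform in cone-like RGB,
        global correction removes it exactly."""
        img = rng.uniform(0.5, 2.0, (10, 12, 3))
        D = np.array([1.7, 0.8, 0.45])
        a = ad.diagonal_correct_global(img, ad.global_gains_of(img))
        b = ad.diagonal_correct_global(img * D, ad.global_gains_of(img * D))
        np.testing.assert_allclose(a, b, atol=1e-9)
        assert ad.median_delta_e(a, b) <= 1e-6

    def test_nonpositive_gains_rejected(self):
        with pytest.raises(ValueError):
            ad.AdaptationField(np.zeros((2, 2, 3)), 1.0)


class TestMedianDeltaE:
    def test_identical_images_give_zero(self, rng):
        img = rng.uniform(0.5, 1.5, (5, 5, 3))
        assert ad.median_delta_e(img, img) == 0.0

    def test_single_outlier_pixel_does_not_move_the_median(self, rng):
        img = rng.uniform(0.9, 1.1, (5, 5, 3))
        other = img.copy()
        base = ad.median_delta_e(img, other * 1.05)
        other_outlier = other * 1.05
        other_outlier[0, 0] *= 40.0
        spiked = ad.median_delta_e(img, other_outlier)
        assert spiked == pytest.approx(base, rel=1e-6)

    def test_three_pixel_toy_median_is_middle_delta(self):
        from gazediet.spectral_core import cam16_ucs_coords, delta_e_ucs

        vc = ViewingConditions()
        a = np.array([[[1.0, 1.0, 1.0], [0.8, 1.1, 0.9], [1.2, 0.7, 1.4]]])
        b = np.array([[[1.0, 1.0, 1.0], [1.0, 1.0, 1.0], [0.9, 1.0, 1.1]]])
        des = [delta_e_ucs(cam16_ucs_coords(a[0, i] * 100.0, vc),
                           cam16_ucs_coords(b[0, i] * 100.0, vc))
               for i in range(3)]
        assert ad.median_delta_e(a, b, vc) == pytest.approx(sorted(des)[1])

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            ad.median_delta_e(np.ones((2, 2, 3)), np.ones((3, 3, 3)))


class TestEvaluationTimes:
    def test_endpoints_are_3_and_14999(self):
        idx = ad.evaluation_times(15000, 6, 3)
        assert idx[0] == 3 and idx[-1] == 14999 and idx.size == 6

    def test_count_two_gives_exactly_the_endpoints(self):
        np.testing.assert_array_equal(ad.evaluation_times(15000, 2, 3),
                                      [3, 14999])

    def test_roughly_constant_consecutive_ratios(self):
        idx = ad.evaluation_times(15000, 6, 3).astype(float)
        ratios = idx[1:] / idx[:-1]
        target = (14999.0 / 3.0) ** (1.0 / 5.0)
        # integer rounding perturbs the smallest indices by at most one frame
        lo = (idx[:-1] * target - 1.0) / (idx[:-1] + 1.0)
        hi = (idx[:-1] * target + 1.0) / (idx[:-1] - 1.0)
        assert np.all(ratios >= lo) and np.all(ratios <= hi)

    def test_infeasible_count_rejected(self):
        with pytest.raises(ValueError):
            ad.evaluation_times(6, 10, 3)


class TestTimecourse:
    def test_uniform_scene_gives_zero_everywhere(self, fixtures):
        s = ad.adaptation_timecourse(fixtures.scenes["uniform"],
                                     fixtures.traces["walk"], tau_s=1.0)
        assert np.all(s.median_dE <= 1e-6)
        assert s.times_s.size == 6

    def test_long_tau_uniform_gaze_converges_toward_global(self, fixtures):
        """With tau -> inf and uniform random gaze the local weighted history
        approaches the global mean, so the final color difference falls well
        below the first."""
        s = ad.adaptation_timecourse(fixtures.scenes["high_variance"],
                                     fixtures.traces["random"], tau_s=1e9)
        assert s.median_dE[-1] < s.median_dE[0]

    def test_confined_gaze_ends_farther_from_global_than_uniform(self, fixtures):
        scene = fixtures.scenes["high_variance"]
        rgb = ad.scene_cam16_rgb(scene, daylight_spd(4000.0))
        sampler = RetinalSampler(rgb, scene.degrees_per_pixel)
        conf = ad.adaptation_timecourse(scene, fixtures.traces["feature"],
                                        tau_s=10.0, sampler=sampler)
        uni = ad.adaptation_timecourse(scene, fixtures.traces["random"],
                                       tau_s=10.0, sampler=sampler)
        assert conf.median_dE[-1] > uni.median_dE[-1]

    def test_slower_time_constant_achieves_lower_minimum(self, fixtures):
        """Replaying the identical trace, the tau = 10 s minimum must not
        exceed the tau = 1 s minimum."""
        scene = fixtures.scenes["high_variance"]
        rgb = ad.scene_cam16_rgb(scene, daylight_spd(4000.0))
        sampler = RetinalSampler(rgb, scene.degrees_per_pixel)
        mins = {}
        for tau in (1.0, 10.0):
            s = ad.adaptation_timecourse(scene, fixtures.traces["walk"],
                                         tau_s=tau, sampler=sampler)
            mins[tau] = s.median_dE.min()
        assert mins[10.0] <= mins[1.0]

    def test_short_trace_rejected(self, fixtures):
        t = fixtures.traces["walk"]
        short = GazeTrace(t.times_s[:10], t.x_deg[:10], t.y_deg[:10],
                          t.valid[:10])
        with pytest.raises(ValueError):
            ad.adaptation_timecourse(fixtures.scenes["uniform"], short,
                                     eval_indices=np.array([3, 50]))


class TestUncorrected:
    def test_same_illuminant_gives_zero(self, fixtures):
        scene = fixtures.scenes["high_variance"]
        ill = fixtures.illuminants["reference_5571k"]
        assert ad.uncorrected_delta_e(scene, ill, 5571.0) == pytest.approx(
            0.0, abs=1e-9)

    def test_flat_achromatic_scene_gives_uniform_shift(self):
        from gazediet.hyperspectral_io import SpectralImage
        from gazediet.spectral_core import CANONICAL_WAVELENGTHS

        scene = SpectralImage(np.full((6, 8, 33), 0.5), CANONICAL_WAVELENGTHS,
                              "reflectance", 0.1)
        ill = daylight_spd(6500.0)
        got = ad.uncorrected_delta_e(scene, ill, 4000.0)
        single = SpectralImage(np.full((1, 1, 33), 0.5), CANONICAL_WAVELENGTHS,
                               "reflectance", 0.1)
        assert got == pytest.approx(ad.uncorrected_delta_e(single, ill, 4000.0))

    def test_larger_cct_gap_yields_larger_shift(self, fixtures):
        scene = fixtures.scenes["high_variance"]
        small = ad.uncorrected_delta_e(scene, daylight_spd(5500.0), 6500.0)
        large = ad.uncorrected_delta_e(scene, daylight_spd(4000.0), 10000.0)
        assert large > small
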