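"""Unit tests for the spectral and colorimetric primitives."""

import numpy as np
import pytest

from gazediet import spectral_core as sc
from gazediet.spectral_core import (
    CANONICAL_WAVELENGTHS,
    Spectrum,
    ViewingConditions,
    cam16_ucs_coords,
    cct_of,
    cone_excitations,
    daylight_spd,
    delta_e_ucs,
    lab_chroma,
    spd_to_xyz,
    synthetic_cone_fundamentals,
    xyz_to_cam16_rgb,
)

GRID = CANONICAL_WAVELENGTHS


def flat(value=1.0) -> Spectrum:
    return Spectrum(GRID, np.full(GRID.size, value))


class TestConeExcitations:
    def test_zero_spectrum_gives_zero_excitations(self):
        q = cone_excitations(flat(0.0))
        assert q == (0.0, 0.0, 0.0)

    def test_linearity_in_radiance(self, rng):
        spd = Spectrum(GRID, rng.uniform(0, 2, GRID.size))
        q1 = np.array(cone_excitations(spd))
        q2 = np.array(cone_excitations(spd.scaled(2.0)))
        np.testing.assert_allclose(q2, 2.0 * q1, rtol=1e-12)

    def test_matches_loop_summation_oracle(self, rng):
        """q must equal a per-band loop of L * S * dlambda to <= 1e-12 rel."""
        fund = synthetic_cone_fundamentals()
        spd = Spectrum(GRID, rng.uniform(0, 1.5, GRID.size))
        expected = [0.0, 0.0, 0.0]
        for i in range(GRID.size):
            expected[0] += spd.values[i] * fund.sL[i] * 10.0
            expected[1] += spd.values[i] * fund.sM[i] * 10.0
            expected[2] += spd.values[i] * fund.sS[i] * 10.0
        got = cone_excitations(spd, fund)
        np.testing.assert_allclose(list(got), expected, rtol=1e-12)

    def test_flat_unit_radiance_equals_band_sums(self):
        fund = synthetic_cone_fundamentals()
        q = cone_excitations(flat(1.0), fund)
        np.testing.assert_allclose(
            list(q),
            [10.0 * fund.sL.sum(), 10.0 * fund.sM.sum(), 10.0 * fund.sS.sum()],
            rtol=1e-12,
        )

    def test_negative_radiance_rejected(self):
        with pytest.raises(ValueError):
            Spectrum(GRID, np.full(GRID.size, -0.1))


class TestDaylight:
    def test_physical_and_finite_at_4000k(self):
        spd = daylight_spd(4000.0)
        assert np.all(np.isfinite(spd.values)) and np.all(spd.values >= 0)

    def test_warmer_daylight_has_redder_energy_balance(self):
        def ratio(spd):
            long_e = spd.values[GRID >= 600].sum()
            short_e = spd.values[GRID <= 500].sum()
            return long_e / short_e

        assert ratio(daylight_spd(4000.0)) > ratio(daylight_spd(10000.0))

    @pytest.mark.parametrize("cct", [4000.0, 5500.0, 6504.0, 7500.0, 10000.0])
    def test_cct_round_trip_within_50k(self, cct):
        est = cct_of(spd_to_xyz(daylight_spd(cct)))
        assert abs(est - cct) <= 50.0

    def test_cct_monotone_in_daylight_phase(self):
        ests = [cct_of(spd_to_xyz(daylight_spd(t))) for t in (4000, 5500, 7500)]
        assert ests[0] < ests[1] < ests[2]

    def test_out_of_validity_range_rejected(self):
        with pytest.raises(ValueError):
            daylight_spd(3000.0)

    def test_far_off_locus_chromaticity_rejected(self):
        with pytest.raises(sc.OutOfGamutError):
            cct_of(np.array([20.0, 100.0, 20.0]))  # saturated green


class TestXYZ:
    def test_zero_spectrum(self):
        np.testing.assert_array_equal(spd_to_xyz(flat(0.0)), np.zeros(3))

    def test_linearity(self, rng):
        spd = Spectrum(GRID, rng.uniform(0, 1, GRID.size))
        np.testing.assert_allclose(spd_to_xyz(spd.scaled(3.0)),
                                   3.0 * spd_to_xyz(spd), rtol=1e-12)

    def test_equal_energy_chromaticity_near_one_third(self):
        xyz = spd_to_xyz(flat(1.0))
        x, y = xyz[0] / xyz.sum(), xyz[1] / xyz.sum()
        assert abs(x - 1.0 / 3.0) < 0.005 and abs(y - 1.0 / 3.0) < 0.005

    def test_matches_summation_oracle(self, rng):
        wl, cmf = sc.cie_1931_cmfs()
        vals = rng.uniform(0, 1, GRID.size)
        k = 100.0 / (cmf[:, 1].sum() * 10.0)
        expected = np.zeros(3)
        for i in range(GRID.size):
            expected += k * vals[i] * cmf[i] * 10.0
        np.testing.assert_allclose(spd_to_xyz(Spectrum(GRID, vals)), expected,
                                   rtol=1e-12)


class TestCam16RGB:
    def test_matrix_entries_match_printed_values(self):
        printed = np.array([
            [0.401, 0.650, -0.0515],
            [-0.250, 1.20, 0.0459],
            [-0.00208, 0.0490, 0.953],
        ])
        np.testing.assert_array_equal(sc.M16, printed)

    def test_unit_basis_vectors_map_to_matrix_columns(self):
        for j, col in enumerate(sc.M16.T):
            e = np.zeros(3)
            e[j] = 1.0
            np.testing.assert_allclose(xyz_to_cam16_rgb(e), col, rtol=0, atol=0)

    def test_zero_maps_to_zero(self):
        np.testing.assert_array_equal(xyz_to_cam16_rgb(np.zeros(3)), np.zeros(3))

    def test_white_maps_to_near_equal_responses(self):
        """A daylight white must give cone-like responses all near 100."""
        xyz = spd_to_xyz(daylight_spd(6504.0))
        rgb = xyz_to_cam16_rgb(xyz * (100.0 / xyz[1]))
        assert np.all(np.abs(rgb - 100.0) < 10.0)


class TestUCS:
    def test_white_is_neutral(self):
        vc = ViewingConditions()
        ucs = cam16_ucs_coords(np.array(vc.white_rgb), vc)
        assert abs(ucs[1]) <= 1e-6 and abs(ucs[2]) <= 1e-6

    def test_half_white_is_neutral_and_darker(self):
        vc = ViewingConditions()
        w = cam16_ucs_coords(np.array(vc.white_rgb), vc)
        g = cam16_ucs_coords(0.5 * np.array(vc.white_rgb), vc)
        assert abs(g[1]) <= 1e-6 and abs(g[2]) <= 1e-6
        assert g[0] < w[0]

    def test_invalid_viewing_conditions_rejected(self):
        with pytest.raises(ValueError):
            ViewingConditions(adapting_luminance=-5.0)
        with pytest.raises(ValueError):
            ViewingConditions(background_relative_luminance=0.0)


class TestDeltaE:
    def test_identity_is_zero(self):
        p = np.array([50.0, 10.0, -5.0])
        assert delta_e_ucs(p, p) == 0.0

    def test_three_four_five_triangle(self):
        assert delta_e_ucs(np.array([50.0, 0.0, 0.0]),
                           np.array([50.0, 3.0, 4.0])) == pytest.approx(5.0)

    def test_is_a_metric_on_random_triples(self, rng):
        pts = rng.normal(scale=20.0, size=(1000, 3, 3))
        for a, b, c in pts:
            dab, dba = delta_e_ucs(a, b), delta_e_ucs(b, a)
            assert dab >= 0 and dab == dba
            assert delta_e_ucs(a, c) <= dab + delta_e_ucs(b, c) + 1e-12


class TestLabChroma:
    def test_achromatic_has_zero_chroma(self):
        white = np.array([95.0, 100.0, 108.0])
        assert lab_chroma(0.2 * white, white) == pytest.approx(0.0, abs=1e-12)

    def test_homogeneity_in_common_scale(self, rng):
        xyz = rng.uniform(10, 90, 3)
        white = np.array([95.0, 100.0, 108.0])
        assert lab_chroma(xyz, white) == pytest.approx(
            lab_chroma(3.7 * xyz, 3.7 * white), rel=1e-12)

    def test_matches_cube_root_formula_oracle(self):
        xyz = np.array([41.0, 35.0, 18.0])
        white = np.array([95.05, 100.0, 108.88])

        def f(t):
            return t ** (1 / 3) if t > (6 / 29) ** 3 else t / (3 * (6 / 29) ** 2) + 4 / 29

        a = 500.0 * (f(xyz[0] / white[0]) - f(xyz[1] / white[1]))
        b = 200.0 * (f(xyz[1] / white[1]) - f(xyz[2] / white[2]))
        assert lab_chroma(xyz, white) == pytest.approx(np.hypot(a, b), abs=1e-9)

    def test_zero_white_rejected(self):
        with pytest.raises(ValueError):
            lab_chroma(np.ones(3), np.array([1.0, 0.0, 1.0]))


class TestApplyIlluminant:
    def make_reflectance(self, value):
        from gazediet.hyperspectral_io import SpectralImage

        return SpectralImage(np.full((4, 5, GRID.size), value), GRID,
                             "reflectance", 0.1)

    def test_unit_reflectance_returns_the_illuminant(self):
        ill = daylight_spd(5500.0)
        out = sc.apply_illuminant(self.make_reflectance(1.0), ill)
        assert out.kind == "radiance"
        np.testing.assert_allclose(out.data[2, 3], ill.values, rtol=1e-12)

    def test_zero_reflectance_returns_zero_radiance(self):
        out = sc.apply_illuminant(self.make_reflectance(0.0), daylight_spd(5500.0))
        assert np.all(out.data == 0.0)

    def test_round_trip_with_reflectance_recovery(self, rng):
        from gazediet.hyperspectral_io import SpectralImage, radiance_to_reflectance

        data = rng.uniform(0.05, 0.95, (6, 7, GRID.size))
        cube = SpectralImage(data, GRID, "reflectance", 0.1)
        ill = daylight_spd(4000.0)
        back = radiance_to_reflectance(sc.apply_illuminant(cube, ill), ill)
        np.testing.assert_allclose(back.data, data, rtol=1e-10)
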