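"""Attenuation-pair decomposition, derived maps and raster plumbing."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from bodysam.config import CalibrationTable
from bodysam.dxa_maps import (AttenuationPair, DegeneratePixelError,
                              body_mask_from_high, compute_rvalue,
                              decompose_tissue, downscale_y, export_8bit,
                              forward_simulate, histogram_equalize, leanness,
                              load_raster, save_raster, total_thickness,
                              upscale_y)


def _uniform_pair(low, high, shape=(4, 5), mask=None):
    low_img = np.full(shape, float(low))
    high_img = np.full(shape, float(high))
    mask = np.ones(shape, bool) if mask is None else mask
    return AttenuationPair(low_img, high_img, body_mask=mask)


class TestRValue:
    def test_equal_channels_give_unit_ratio(self):
        r = compute_rvalue(_uniform_pair(0.7, 0.7))
        assert np.allclose(r, 1.0)

    def test_pure_lean_ratio_is_coefficient_ratio(self, calib):
        # a body of pure lean tissue has R = mu_lean_low/mu_lean_high at
        # every thickness: composition, not thickness, sets the ratio
        thick = np.linspace(1.0, 40.0, 12).reshape(3, 4)
        pair = forward_simulate(np.zeros_like(thick), thick, calib)
        r = compute_rvalue(pair)
        assert np.allclose(r[pair.body_mask],
                           calib.mu_lean_low / calib.mu_lean_high, atol=1e-12)

    def test_empty_mask_is_all_no_data(self):
        pair = _uniform_pair(0.5, 0.0, mask=np.zeros((4, 5), bool))
        r = compute_rvalue(pair)
        assert np.isnan(r).all()

    def test_zero_high_on_mask_names_coordinates(self):
        high = np.ones((4, 5))
        high[2, 3] = 0.0
        pair = AttenuationPair(np.ones((4, 5)), high,
                               body_mask=np.ones((4, 5), bool))
        with pytest.raises(DegeneratePixelError, match=r"y=2, x=3"):
            compute_rvalue(pair)


class TestDecompose:
    def test_zero_attenuation_gives_zero_thickness(self):
        fat, lean, n = decompose_tissue(_uniform_pair(0.0, 0.0))
        assert fat.max() == lean.max() == 0.0 and n == 0

    def test_forward_round_trip(self, calib, rng):
        tf = rng.uniform(0, 15, (20, 30))
        tl = rng.uniform(0, 25, (20, 30))
        pair = forward_simulate(tf, tl, calib)
        fat, lean, n_clamped = decompose_tissue(pair, calib)
        m = pair.body_mask
        assert np.abs(fat[m] - tf[m]).max() <= 1e-10
        assert np.abs(lean[m] - tl[m]).max() <= 1e-10
        assert n_clamped == 0

    def test_constant_round_trip_exact(self, calib):
        pair = forward_simulate(np.full((3, 3), 5.0), np.full((3, 3), 10.0), calib)
        fat, lean, _ = decompose_tissue(pair, calib)
        assert np.abs(fat - 5.0).max() <= 1e-10
        assert np.abs(lean - 10.0).max() <= 1e-10

    def test_unphysical_pair_clamped_and_counted(self, calib):
        # attenuations only consistent with tf = -1: solved fat is negative,
        # clamped to zero, and every affected pixel is counted
        tf, tl = -1.0, 10.0
        low = np.full((2, 2), calib.mu_fat_low * tf + calib.mu_lean_low * tl)
        high = np.full((2, 2), calib.mu_fat_high * tf + calib.mu_lean_high * tl)
        pair = AttenuationPair(low, high, body_mask=np.ones((2, 2), bool))
        fat, lean, n_clamped = decompose_tissue(pair, calib)
        assert fat.max() == 0.0
        assert n_clamped == 4

    def test_singular_calibration_rejected_before_pixel_work(self):
        with pytest.raises(ValueError, match="singular"):
            CalibrationTable(mu_fat_low=0.2, mu_fat_high=0.1,
                             mu_lean_low=0.4, mu_lean_high=0.2)


class TestThicknessLeanness:
    def test_additivity(self):
        tf = np.full((3, 3), 5.0)
        tl = np.full((3, 3), 10.0)
        assert np.all(total_thickness(tf, tl) == 15.0)
        assert np.all(total_thickness(np.zeros((2, 2)), np.zeros((2, 2))) == 0)

    def test_mass_form_equals_direct_sum(self, calib, rng):
        # thickness via mass/(density*pixel area) agrees with the direct
        # fat+lean sum on a forward-simulated field
        tf = rng.uniform(0, 10, (8, 8))
        tl = rng.uniform(0, 20, (8, 8))
        area = 0.2 * 1.3  # cm^2
        fat_mass = tf * calib.density_fat * area
        lean_mass = tl * calib.density_lean * area
        via_mass = fat_mass / (calib.density_fat * area) \
            + lean_mass / (calib.density_lean * area)
        assert np.allclose(via_mass, total_thickness(tf, tl), atol=1e-12)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError, match="mismatch"):
            total_thickness(np.zeros((2, 2)), np.zeros((3, 2)))

    @pytest.mark.parametrize("tf, tl, expected",
                             [(0.0, 7.0, 1.0), (4.0, 4.0, 0.5), (5.0, 15.0, 0.75)])
    def test_leanness_values(self, tf, tl, expected):
        out = leanness(np.full((2, 2), tf), np.full((2, 2), tl))
        assert np.allclose(out, expected)

    def test_leanness_zero_total_on_mask_raises(self):
        mask = np.ones((2, 2), bool)
        with pytest.raises(DegeneratePixelError):
            leanness(np.zeros((2, 2)), np.zeros((2, 2)), mask)

    @given(st.floats(0.01, 50), st.floats(0.01, 50))
    def test_leanness_in_unit_interval(self, tf, tl):
        out = leanness(np.full((2, 2), tf), np.full((2, 2), tl))
        assert 0.0 <= out.min() and out.max() <= 1.0


class TestUpscaleY:
    def test_native_grid_reaches_square_resolution(self):
        out = upscale_y(np.zeros((150, 327)), 6.5)
        assert out.shape == (975, 327)

    def test_factor_one_is_bitwise_identity(self, rng):
        img = rng.normal(size=(10, 7))
        out = upscale_y(img, 1.0)
        assert np.array_equal(out, img)

    def test_constant_preserved(self):
        out = upscale_y(np.full((8, 4), 3.25), 6.5)
        assert np.all(out == 3.25)

    def test_linear_ramp_round_trip(self):
        # a bilinear-representable ramp survives upscale + downscale
        rows = np.arange(20, dtype=float)
        ramp = np.tile(2.0 * rows[:, None] + 1.0, (1, 5))
        up = upscale_y(ramp, 6.5)
        back = downscale_y(up, 6.5)
        assert np.abs(back - ramp).max() <= 1e-6

    def test_non_integral_output_rejected(self):
        with pytest.raises(ValueError, match="not integral"):
            upscale_y(np.zeros((7, 3)), 6.5)

    def test_nearest_variant_preserves_values(self):
        img = np.arange(12, dtype=float).reshape(6, 2)
        out = upscale_y(img, 2.0, interpolation="nearest")
        assert set(np.unique(out)) <= set(np.unique(img))


class TestExport8Bit:
    def test_range_endpoints_and_midpoint(self):
        vals = np.array([[0.0, 1.0, 0.5, -0.2, 1.3]])
        out = export_8bit(vals, 0.0, 1.0)
        # midpoint maps to 127.5 which rounds half away from zero to 128
        assert out.tolist() == [[0, 255, 128, 0, 255]]

    def test_invalid_range_rejected(self):
        with pytest.raises(ValueError):
            export_8bit(np.zeros((2, 2)), 1.0, 1.0)


class TestHistogramEqualize:
    def test_constant_raster_stays_constant(self):
        out = histogram_equalize(np.full((4, 4), 2.0), np.ones((4, 4), bool))
        assert np.allclose(out, 1.0)

    def test_two_level_cdf(self):
        img = np.zeros((2, 4))
        img[0, 0] = 0.0
        img[img == 0] = 1.0
        img[0, :2] = 0.0  # 2 of 8 pixels low -> CDF 0.25, rest 1.0
        out = histogram_equalize(img, np.ones((2, 4), bool))
        assert np.allclose(np.sort(np.unique(out)), [0.25, 1.0])

    def test_order_preserved_and_off_mask_untouched(self, rng):
        img = rng.normal(size=(6, 6))
        mask = np.zeros((6, 6), bool)
        mask[:, :3] = True
        out = histogram_equalize(img, mask)
        a = img[mask]
        b = out[mask]
        assert np.array_equal(np.argsort(a, kind="stable"),
                              np.argsort(b, kind="stable"))
        assert np.array_equal(out[~mask], img[~mask])

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            histogram_equalize(np.ones((2, 2)), np.zeros((2, 2), bool))


class TestMaskAndIO:
    def test_largest_component_kept(self):
        high = np.zeros((10, 10))
        high[1:6, 1:6] = 1.0   # 25 px blob
        high[8:10, 8:10] = 1.0  # 4 px blob
        mask = body_mask_from_high(high)
        assert mask[2, 2] and not mask[8, 8]

    def test_raster_round_trip(self, tmp_path, rng):
        img = rng.uniform(0, 30, (12, 9))
        save_raster(tmp_path / "t.tif", img, (2.0, 13.0),
                    mask=img > 15, value_range=(0.0, 30.0))
        back, pixel, mask, _ = load_raster(tmp_path / "t.tif")
        assert pixel == (2.0, 13.0)
        assert np.abs(back - img).max() <= 30.0 / 65535 + 1e-9
        assert np.array_equal(mask, img > 15)
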