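"""Background fitting, despiking and per-line calibration."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from voxelgram import correct
from voxelgram.correct import (BackgroundRegion, CalibrationFactorSeries,
                               StandardMeasurement)
from voxelgram.rawio import ChannelImage


def image(values, **kw):
    return ChannelImage(values=np.asarray(values, dtype=float),
                        isotope=kw.pop("isotope", "31P"), **kw)


CORNERS = [BackgroundRegion(rect=(0, 0, 4, 4)),
           BackgroundRegion(rect=(0, 16, 4, 4)),
           BackgroundRegion(rect=(16, 0, 4, 4)),
           BackgroundRegion(rect=(16, 16, 4, 4))]


class TestBackground:
    def test_constant_image_gives_constant_surface(self):
        img = image(np.full((20, 20), 100.0))
        model = correct.fit_background(img, CORNERS, order=2)
        np.testing.assert_allclose(model.surface, 100.0, atol=1e-9)
        assert model.fit_residual < 1e-9

    def test_linear_ramp_recovered_from_two_corner_regions(self):
        yy, xx = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        ramp = 2.0 * xx + 3.0
        img = image(ramp)
        regions = [BackgroundRegion(rect=(0, 0, 4, 4)),
                   BackgroundRegion(rect=(16, 16, 4, 4))]
        model = correct.fit_background(img, regions, order=1)
        assert np.abs(model.surface - ramp).max() < 1e-6

    def test_order2_surface_recovered_exactly(self):
        yy, xx = np.meshgrid(np.arange(24), np.arange(24), indexing="ij")
        bg = 5.0 + 0.3 * xx + 0.2 * yy + 0.01 * xx * yy + 0.02 * xx ** 2
        model = correct.fit_background(image(bg), CORNERS, order=2)
        assert np.abs(model.surface - bg).max() < 1e-6

    def test_underdetermined_fit_reports_required_pixels(self):
        img = image(np.zeros((20, 20)))
        with pytest.raises(ValueError, match=r">= 6"):
            correct.fit_background(
                img, [BackgroundRegion(rect=(0, 0, 1, 2))], order=2)

    def test_polygon_region_accepted(self):
        img = image(np.full((10, 10), 7.0))
        reg = BackgroundRegion(polygon=[(0, 0), (4, 0), (4, 4), (0, 4)])
        model = correct.fit_background(img, [reg], order=0)
        np.testing.assert_allclose(model.surface, 7.0, atol=1e-9)

    def test_subtract_identity_and_clamp(self):
        img = image(np.full((20, 20), 50.0))
        model = correct.fit_background(img, CORNERS, order=2)
        out = correct.subtract_background(img, model)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-9)
        low = image(np.full((20, 20), 5.0))
        model10 = correct.fit_background(image(np.full((20, 20), 10.0)),
                                         CORNERS, order=0)
        assert correct.subtract_background(low, model10).values[0, 0] \
            == pytest.approx(-5.0)
        assert correct.subtract_background(
            low, model10, clamp_negative=True).values[0, 0] == 0.0

    def test_region_mean_zero_after_subtraction(self):
        # least-squares residuals over the fitted pixels have zero mean
        yy, xx = np.meshgrid(np.arange(20), np.arange(20), indexing="ij")
        bg = 1.0 + 0.5 * xx + 0.25 * yy ** 2
        out = correct.subtract_background(
            image(bg), correct.fit_background(image(bg), CORNERS, order=2))
        region_mask = np.zeros((20, 20), dtype=bool)
        for r in CORNERS:
            region_mask |= r.pixel_mask((20, 20))
        assert abs(out.values[region_mask].mean()) < 1e-9

    def test_shape_mismatch_raises(self):
        model = correct.fit_background(image(np.zeros((20, 20))), CORNERS)
        with pytest.raises(ValueError):
            correct.subtract_background(image(np.zeros((5, 5))), model)


def brute_force_despike(values, window, factor, floor):
    """Independent per-pixel reference for the despiking rule."""
    values = np.asarray(values, dtype=float)
    H, W = values.shape
    half = window // 2
    out = values.copy()
    n = 0
    for r in range(H):
        for c in range(W):
            patch = [values[i, j]
                     for i in range(max(0, r - half), min(H, r + half + 1))
                     for j in range(max(0, c - half), min(W, c + half + 1))
                     if (i, j) != (r, c)]
            med = float(np.median(patch))
            if values[r, c] > factor * med + floor:
                out[r, c] = med
                n += 1
    return out, n


class TestDespike:
    def test_constant_image_unchanged(self):
        out, n = correct.despike(image(np.full((12, 12), 10.0)))
        assert n == 0
        np.testing.assert_array_equal(out.values, 10.0)

    def test_single_spike_replaced_by_neighbourhood_median(self):
        vals = np.full((15, 15), 10.0)
        vals[7, 7] = 1e6
        out, n = correct.despike(image(vals))
        assert n == 1
        assert out.values[7, 7] == 10.0

    def test_corner_spike_uses_truncated_window(self):
        rng = np.random.default_rng(5)
        vals = 50.0 + rng.random((12, 12))
        vals[0, 0] = 1e5
        expected, n_exp = brute_force_despike(vals, 9, 5.0, 0.0)
        out, n = correct.despike(image(vals))
        assert n == n_exp == 1
        np.testing.assert_allclose(out.values, expected)

    @pytest.mark.parametrize("shape", [(9, 9), (14, 23)])
    def test_matches_brute_force_oracle(self, shape):
        rng = np.random.default_rng(11)
        vals = 20.0 + 5.0 * rng.random(shape)
        for r, c in [(2, 3), (shape[0] - 1, shape[1] - 2)]:
            vals[r, c] = 5000.0
        expected, n_exp = brute_force_despike(vals, 9, 5.0, 0.0)
        out, n = correct.despike(image(vals))
        assert n == n_exp
        np.testing.assert_allclose(out.values, expected)

    def test_idempotent_on_isolated_spikes(self):
        rng = np.random.default_rng(7)
        vals = 30.0 + rng.random((20, 20))
        for r, c in [(3, 3), (10, 15), (17, 4)]:
            vals[r, c] = 4000.0
        once, n1 = correct.despike(image(vals))
        twice, n2 = correct.despike(once)
        assert n1 == 3 and n2 == 0
        np.testing.assert_array_equal(once.values, twice.values)

    def test_even_or_tiny_window_rejected(self):
        img = image(np.zeros((5, 5)))
        with pytest.raises(ValueError):
            correct.despike(img, window=8)
        with pytest.raises(ValueError):
            correct.despike(img, window=1)


class TestCalibration:
    def test_constant_sensitivity_gives_constant_factor(self):
        pre = StandardMeasurement("56Fe", mean_cps=100.0, concentration=20.0,
                                  position="pre")
        post = StandardMeasurement("56Fe", mean_cps=100.0, concentration=20.0,
                                   position="post")
        series = correct.line_calibration_factors(pre, post, n_rows=4)
        np.testing.assert_allclose(series.factors, 0.2)

    def test_linear_interpolation_over_rows(self):
        pre = StandardMeasurement("56Fe", 2000.0, 10.0, "pre")
        post = StandardMeasurement("56Fe", 4000.0, 10.0, "post")
        series = correct.line_calibration_factors(pre, post, n_rows=3)
        np.testing.assert_allclose(series.factors,
                                   [1 / 200.0, 1 / 300.0, 1 / 400.0])

    def test_time_based_interpolation(self):
        pre = StandardMeasurement("56Fe", 2000.0, 10.0, "pre", timestamp=0.0)
        post = StandardMeasurement("56Fe", 4000.0, 10.0, "post", timestamp=100.0)
        ts = np.array([0.0, 25.0, 100.0])
        series = correct.line_calibration_factors(pre, post, 3,
                                                  row_timestamps=ts)
        np.testing.assert_allclose(series.factors,
                                   [1 / 200.0, 1 / 250.0, 1 / 400.0])

    def test_zero_sensitivity_and_isotope_mismatch_raise(self):
        good = StandardMeasurement("56Fe", 100.0, 10.0, "pre")
        zero = StandardMeasurement("56Fe", 0.0, 10.0, "post")
        with pytest.raises(ValueError, match="sensitivity"):
            correct.line_calibration_factors(good, zero, 3)
        other = StandardMeasurement("66Zn", 100.0, 10.0, "post")
        with pytest.raises(ValueError, match="mismatch"):
            correct.line_calibration_factors(good, other, 3)

    def test_apply_calibration_row_arithmetic(self):
        img = image(np.full((2, 3), 600.0), isotope="56Fe")
        series = CalibrationFactorSeries(
            isotope="56Fe", factors=np.array([1 / 300.0, 1 / 300.0]),
            sensitivity_pre=300.0, sensitivity_post=300.0)
        out = correct.apply_calibration(img, series)
        np.testing.assert_allclose(out.values, 2.0)
        assert out.units == "ug/g"
        zero = correct.apply_calibration(
            image(np.zeros((2, 3)), isotope="56Fe"), series)
        np.testing.assert_array_equal(zero.values, 0.0)
        assert zero.units == "ug/g"

    def test_units_and_length_guards(self):
        series = CalibrationFactorSeries("56Fe", np.ones(2), 1.0, 1.0)
        with pytest.raises(ValueError, match="CPS"):
            correct.apply_calibration(
                image(np.ones((2, 2)), isotope="56Fe", units="ug/g"), series)
        with pytest.raises(ValueError, match="length"):
            correct.apply_calibration(
                image(np.ones((3, 2)), isotope="56Fe"), series)

    def test_channel_without_standard_passes_through_flagged(self):
        channels = {
            "56Fe": image(np.full((2, 2), 100.0), isotope="56Fe"),
            "55Mn": image(np.full((2, 2), 40.0), isotope="55Mn"),
        }
        stds = [StandardMeasurement("56Fe", 200.0, 10.0, "pre"),
                StandardMeasurement("56Fe", 200.0, 10.0, "post")]
        out, unquantified = correct.calibrate_run(channels, stds)
        assert unquantified == ["55Mn"]
        assert out["55Mn"].units == "CPS"
        assert out["55Mn"].meta.get("unquantified") is True
        np.testing.assert_array_equal(out["55Mn"].values, 40.0)
        assert out["56Fe"].units == "ug/g"
        np.testing.assert_allclose(out["56Fe"].values, 5.0)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(s_pre=st.floats(10.0, 1e4), s_post=st.floats(10.0, 1e4),
           seed=st.integers(0, 100))
    def test_calibration_exactly_invertible(self, s_pre, s_post, seed):
        rng = np.random.default_rng(seed)
        vals = rng.random((6, 5)) * 1e4
        pre = StandardMeasurement("56Fe", s_pre * 10.0, 10.0, "pre")
        post = StandardMeasurement("56Fe", s_post * 10.0, 10.0, "post")
        series = correct.line_calibration_factors(pre, post, 6)
        out = correct.apply_calibration(image(vals, isotope="56Fe"), series)
        back = out.values / series.factors[:, None]
        np.testing.assert_allclose(back, vals, rtol=1e-12)

    def test_known_drift_fully_removed_noise_free(self):
        # image rows scaled by a linear sensitivity ramp; calibration from
        # the bracketing standards must reconstruct the concentrations
        rng = np.random.default_rng(3)
        conc = rng.random((10, 8)) * 5.0
        sens = np.linspace(400.0, 250.0, 10)
        cps = conc * sens[:, None]
        pre = StandardMeasurement("66Zn", sens[0] * 15.0, 15.0, "pre")
        post = StandardMeasurement("66Zn", sens[-1] * 15.0, 15.0, "post")
        series = correct.line_calibration_factors(pre, post, 10)
        out = correct.apply_calibration(image(cps, isotope="66Zn"), series)
        np.testing.assert_allclose(out.values, conc, rtol=1e-6)
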