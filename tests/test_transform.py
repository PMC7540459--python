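import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from firecast.io import month_index
from firecast.transform import (
    MonthlyClimatology,
    actual_vp,
    inverse_transform,
    monthly_climatology,
    saturation_vp,
    standardize_vpd,
    transform,
    vpd_field,
)

TWO_TANH_ONE = 1.5231883119115297  # 2*tanh(1)


def series_of(values, start_year=2000):
    return pd.Series(values, index=month_index(start_year, len(values)))


class TestClimatology:
    def test_constant_series(self):
        clim = monthly_climatology(series_of(np.full(48, 3.0)), (2000, 2003))
        np.testing.assert_allclose(clim.mean, 3.0)
        np.testing.assert_allclose(clim.sd, 0.0)

    def test_two_year_toy_uses_sample_denominator(self):
        vals = np.zeros(24)
        vals[0], vals[12] = 1.0, 3.0  # the two Januaries
        clim = monthly_climatology(series_of(vals), (2000, 2001))
        assert clim.mean[0] == pytest.approx(2.0)
        assert clim.sd[0] == pytest.approx(np.sqrt(2.0))  # ddof=1

    def test_data_outside_window_ignored(self):
        vals = np.arange(60.0)
        base = monthly_climatology(series_of(vals), (2000, 2003))
        vals2 = vals.copy()
        vals2[48:] = 1e6  # perturb the fifth year only
        again = monthly_climatology(series_of(vals2), (2000, 2003))
        np.testing.assert_array_equal(base.mean, again.mean)
        np.testing.assert_array_equal(base.sd, again.sd)

    def test_single_year_window_is_insufficient(self):
        with pytest.raises(ValueError, match="fewer than 2"):
            monthly_climatology(series_of(np.ones(12)), (2000, 2000))


class TestAnomalyTransform:
    CLIM = MonthlyClimatology(np.full(12, 5.0), np.full(12, 1.0), (2000, 2001))

    def test_mean_maps_to_zero_and_two_sd_to_frozen_value(self):
        y = series_of([5.0, 7.0] + [5.0] * 10)
        out = transform(y, self.CLIM)
        assert out.iloc[0] == pytest.approx(0.0)
        assert out.iloc[1] == pytest.approx(TWO_TANH_ONE)

    def test_extreme_values_saturate_below_two(self):
        y = series_of([1e12] * 12)
        out = transform(y, self.CLIM)
        assert np.all(out.values <= 2.0) and out.iloc[0] == pytest.approx(2.0)

    def test_zero_sd_months_map_to_zero_both_ways(self):
        clim = MonthlyClimatology(np.full(12, 5.0), np.zeros(12), (2000, 2001))
        y = series_of(np.linspace(0, 10, 12))
        assert np.all(transform(y, clim).values == 0.0)
        back = inverse_transform(series_of(np.zeros(12)), clim)
        np.testing.assert_allclose(back.values, 5.0)

    def test_inverse_of_frozen_example(self):
        back = inverse_transform(series_of([TWO_TANH_ONE]), self.CLIM)
        assert back.iloc[0] == pytest.approx(7.0, abs=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(-1.9, 1.9), min_size=1, max_size=24))
    def test_round_trip_identity_on_open_range(self, anoms):
        s = series_of(anoms)
        again = transform(inverse_transform(s, self.CLIM), self.CLIM)
        np.testing.assert_allclose(again.values, s.values, atol=1e-9)

    @settings(max_examples=60, deadline=None)
    @given(st.lists(st.floats(0, 1e6), min_size=12, max_size=12))
    def test_transform_always_bounded_and_monotone(self, vals):
        out = transform(series_of(vals), self.CLIM).values
        assert np.all(np.abs(out) <= 2.0)
        order = np.argsort(vals)
        assert np.all(np.diff(out[order]) >= -1e-12)

    def test_back_transformed_forecasts_non_negative(self):
        back = inverse_transform(series_of([-1.99] * 12), self.CLIM)
        assert np.all(back.values >= 0.0)


class TestVPDFormulas:
    def test_saturation_at_zero_celsius_is_reference_constant(self):
        assert saturation_vp(0.0) == 6.112

    def test_saturation_at_twenty_celsius(self):
        assert saturation_vp(20.0) == pytest.approx(23.36947123406443)

    def test_saturation_strictly_increasing(self):
        t = np.linspace(-40, 50, 200)
        assert np.all(np.diff(saturation_vp(t)) > 0)

    def test_saturation_domain_error(self):
        with pytest.raises(ValueError):
            saturation_vp(-250.0)

    def test_actual_vp_examples_and_linearity(self):
        assert actual_vp(0.0, 1000.0) == 0.0
        assert actual_vp(0.00622, 1000.0) == pytest.approx(10.0)
        assert actual_vp(2 * 0.003, 1000.0) == pytest.approx(
            2 * actual_vp(0.003, 1000.0))
        with pytest.raises(ValueError):
            actual_vp(-0.001, 1000.0)


class TestVPDField:
    TIME = month_index(2000, 2)

    def test_saturated_air_gives_zero(self):
        t = np.full((2, 2, 2), 15.0)
        es = saturation_vp(15.0)
        qv = np.full((2, 2, 2), es * 0.622 / 1000.0)
        ps = np.full((2, 2, 2), 1000.0)
        out = vpd_field(t, qv, ps, self.TIME)
        np.testing.assert_allclose(out.values, 0.0, atol=1e-12)

    def test_uniform_fields_match_scalar_formula(self):
        t = np.full((2, 3, 3), 25.0)
        qv = np.full((2, 3, 3), 0.008)
        ps = np.full((2, 3, 3), 980.0)
        out = vpd_field(t, qv, ps, self.TIME)
        expect = saturation_vp(25.0) - actual_vp(0.008, 980.0)
        np.testing.assert_allclose(out.values, expect)

    def test_block_average_onto_coarser_grid(self):
        # 2x2 source cells -> one target cell, cosine-latitude weighted
        t = np.zeros((1, 2, 2))
        t[0] = [[10.0, 12.0], [14.0, 16.0]]
        qv = np.zeros((1, 2, 2))
        ps = np.full((1, 2, 2), 1000.0)
        out = vpd_field(t, qv, ps, month_index(2000, 1),
                        source_lat0=40.0, coarsen_factor=2)
        lat = 40.0 + 0.25 + 0.5 * np.arange(2)
        w = np.cos(np.deg2rad(lat))
        es = saturation_vp(t[0])
        expect = (es[0] * w[0] + es[1] * w[1]).sum() / (2 * w.sum())
        assert out.values[0, 0, 0] == pytest.approx(expect)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="shapes"):
            vpd_field(np.zeros((2, 2, 2)), np.zeros((2, 2, 3)),
                      np.zeros((2, 2, 2)), self.TIME)


class TestStandardizeVPD:
    def test_examples(self):
        clim = MonthlyClimatology(np.full(12, 10.0), np.full(12, 2.0),
                                  (2000, 2001))
        out = standardize_vpd(series_of([10.0, 14.0]), clim)
        assert out.iloc[0] == 0.0 and out.iloc[1] == pytest.approx(2.0)

    def test_unit_variance_per_month_on_long_input(self, rng):
        n = 1200
        s = series_of(10.0 + 3.0 * rng.standard_normal(n))
        clim = monthly_climatology(s, (2000, 2099))
        z = standardize_vpd(s, clim)
        for m in range(1, 13):
            vals = z[z.index.month == m]
            assert vals.std(ddof=1) == pytest.approx(1.0, abs=1e-9)
            assert vals.mean() == pytest.approx(0.0, abs=1e-9)
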