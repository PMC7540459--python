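import numpy as np
import pandas as pd
import pytest

from firecast.io import month_index
from firecast.synth import (
    BlockCoupling,
    SynthConfig,
    gen_country_mask,
    gen_emission_field,
    gen_oci_set,
    gen_vpd_field,
    seasonal_factors,
)


def lag1_autocorr(x):
    return float(np.corrcoef(x[1:], x[:-1])[0, 1])


class TestOCISet:
    @pytest.mark.parametrize("phi", [0.0, 0.8])
    def test_ar1_lag1_autocorrelation_matches_theory(self, phi):
        ocis = gen_oci_set(1, 10_000, ar1_phi=phi, innovation_sd=1.0, seed=5)
        assert abs(lag1_autocorr(ocis.data["OCI01"].values) - phi) < 0.05

    def test_deterministic_and_named(self):
        a = gen_oci_set(3, 60, seed=11)
        b = gen_oci_set(3, 60, seed=11)
        pd.testing.assert_frame_equal(a.data, b.data)
        assert a.names == ["OCI01", "OCI02", "OCI03"]

    def test_zero_mean(self):
        ocis = gen_oci_set(2, 20_000, ar1_phi=0.5, seed=1)
        assert abs(ocis.data["OCI01"].mean()) < 0.1

    @pytest.mark.parametrize("kwargs", [
        {"ar1_phi": 1.0}, {"ar1_phi": np.nan}, {"innovation_sd": -1.0},
        {"n_months": 12},
    ])
    def test_invalid_parameters_rejected(self, kwargs):
        base = dict(n_indices=1, n_months=48)
        base.update(kwargs)
        with pytest.raises(ValueError):
            gen_oci_set(**base)


class TestEmissionField:
    def test_pure_seasonal_cycle_repeats_exactly(self):
        ocis = gen_oci_set(1, 8 * 12, seed=0)
        cfg = SynthConfig(n_lat=2, n_lon=2, n_years=8, noise_sd=0.0, seed=0)
        field, _ = gen_emission_field(cfg, ocis)
        years = field.values.reshape(8, 12, 2, 2)
        for k in range(1, 8):
            np.testing.assert_allclose(years[k], years[0], rtol=1e-12)

    def test_seasonal_factor_peaks_at_peak_month_with_mean_one(self):
        f = seasonal_factors(peak_month=7, concentration=3.0)
        assert np.argmax(f) == 6
        assert f.mean() == pytest.approx(1.0)

    def test_planted_lag_is_argmax_of_cross_correlation(self):
        n_years = 60  # long series so the sampling noise is small
        ocis = gen_oci_set(1, n_years * 12, ar1_phi=0.5, innovation_sd=1.0, seed=2)
        cfg = SynthConfig(
            n_lat=1, n_lon=1, n_years=n_years, noise_sd=0.2, seed=2,
            seasonal_concentration=0.0,  # flat cycle keeps log finite
            oci_coupling=[BlockCoupling((0, 1), (0, 1), "OCI01", 3, 0.6)])
        field, truth = gen_emission_field(cfg, ocis)
        y = np.log(field.values[:, 0, 0])
        months = field.time.month.values
        anom = np.zeros_like(y)
        for m in range(1, 13):
            anom[months == m] = y[months == m] - y[months == m].mean()
        x = ocis.data["OCI01"].values
        rs = [np.corrcoef(anom[k:], x[:len(x) - k])[0, 1] for k in range(12)]
        assert np.argmax(np.abs(rs)) == truth.couplings[0].lag == 3

    def test_zero_inflation_one_gives_all_zero_field(self):
        ocis = gen_oci_set(1, 48, seed=0)
        cfg = SynthConfig(n_lat=2, n_lon=2, n_years=4, zero_inflation_prob=1.0,
                          seed=0)
        field, _ = gen_emission_field(cfg, ocis)
        assert np.all(field.values == 0)

    def test_trend_slope_recovered_by_ols_within_two_se(self):
        ocis = gen_oci_set(1, 30 * 12, seed=9)
        slope = 0.04
        cfg = SynthConfig(n_lat=1, n_lon=1, n_years=30, noise_sd=0.1,
                          trend_slope_map=slope, base_emission_map=1.2, seed=9)
        field, _ = gen_emission_field(cfg, ocis)
        _, annual = field.annual_sums()
        y = annual[:, 0, 0]
        t = np.arange(len(y), dtype=float)
        X = np.column_stack([np.ones_like(t), t])
        beta, res_, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        se = np.sqrt(resid @ resid / (len(y) - 2) / ((t - t.mean()) ** 2).sum())
        # planted fractional slope corresponds to base * slope Tg/yr per year
        assert abs(beta[1] - 1.2 * slope) < 2 * se

    def test_grid_growth_keeps_existing_cells(self):
        ocis = gen_oci_set(1, 48, seed=4)
        small = SynthConfig(n_lat=2, n_lon=2, n_years=4, seed=4)
        big = SynthConfig(n_lat=3, n_lon=3, n_years=4, seed=4)
        f1, _ = gen_emission_field(small, ocis)
        f2, _ = gen_emission_field(big, ocis)
        np.testing.assert_array_equal(f1.values, f2.values[:, :2, :2])

    def test_negative_base_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            SynthConfig(n_lat=1, n_lon=1, n_years=4, base_emission_map=-1.0)

    def test_unknown_oci_rejected(self):
        ocis = gen_oci_set(1, 48, seed=0)
        cfg = SynthConfig(n_lat=1, n_lon=1, n_years=4,
                          oci_coupling=[BlockCoupling((0, 1), (0, 1), "NOPE", 2, 1.0)])
        with pytest.raises(ValueError, match="unknown OCI"):
            gen_emission_field(cfg, ocis)


class TestVPDField:
    def _field(self, noise_sd, seed=6, n_years=25):
        ocis = gen_oci_set(1, n_years * 12, seed=seed)
        cfg = SynthConfig(n_lat=1, n_lon=1, n_years=n_years, noise_sd=0.3,
                          seed=seed)
        field, _ = gen_emission_field(cfg, ocis)
        vpd = gen_vpd_field(cfg, field, seed=seed, shift=1, scale=1.0,
                            noise_sd=noise_sd)
        return field, vpd

    @staticmethod
    def _xcorr_with_vpd(field, vpd, max_lag=6):
        months = field.time.month.values
        y = field.values[:, 0, 0].copy()
        v = vpd.values[:, 0, 0].copy()
        for m in range(1, 13):
            y[months == m] -= y[months == m].mean()
            v[months == m] -= v[months == m].mean()
        return [np.corrcoef(y[k:], v[:len(v) - k])[0, 1] for k in range(max_lag)]

    def test_noise_free_correlation_peaks_at_planted_shift(self):
        field, vpd = self._field(noise_sd=0.0)
        rs = self._xcorr_with_vpd(field, vpd)
        assert np.argmax(np.abs(rs)) == 1

    def test_noise_shrinks_correlation_monotonically(self):
        r_by_noise = []
        for noise in (0.0, 2.0, 50.0):
            field, vpd = self._field(noise_sd=noise)
            r_by_noise.append(abs(self._xcorr_with_vpd(field, vpd)[1]))
        assert r_by_noise[0] > r_by_noise[1] > r_by_noise[2]
        assert r_by_noise[2] < 0.2

    def test_reproducible_and_non_negative(self):
        f1, v1 = self._field(noise_sd=0.5)
        f2, v2 = self._field(noise_sd=0.5)
        np.testing.assert_array_equal(v1.values, v2.values)
        assert v1.values.min() >= 0


class TestCountryMask:
    def test_single_country_constant(self):
        assert np.all(gen_country_mask(4, 6, 1) == 1)

    def test_two_countries_split_at_meridian(self):
        mask = gen_country_mask(4, 8, 2)
        assert np.all(mask[:, :4] == 1) and np.all(mask[:, 4:] == 2)

    def test_codes_cover_exactly_one_to_n(self):
        mask = gen_country_mask(5, 9, 3)
        assert sorted(np.unique(mask)) == [1, 2, 3]
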