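import numpy as np
import pytest

from firecast.io import EmissionField, month_index
from firecast.regions import (
    FCRCriteria,
    aggregate_series,
    build_multires_grid,
    criteria_pass,
    derive_e_min,
    derive_fcrs,
)
from firecast.synth import gen_country_mask

from oracle_regions import oracle_fcrs


def field_from_annual(annual, start_year=1997, lat0=-8.0):
    """Spread per-cell annual totals evenly over the 12 months of each year."""
    n_years, n_lat, n_lon = annual.shape
    monthly = np.repeat(annual / 12.0, 12, axis=0)
    return EmissionField(monthly, month_index(start_year, 12 * n_years), lat0=lat0)


class TestMultiResGrid:
    def test_global_grid_truncates_northern_eight_degree_row(self):
        grid = build_multires_grid(180, 360)
        rows = sorted({(b[0].start, b[0].stop) for b in grid.level_blocks("8")})
        assert len(rows) == 23
        assert rows[-1] == (176, 180)  # 4-degree-tall northernmost band
        full = [r for r in rows if r[1] - r[0] == 8]
        assert len(full) == 22

    def test_16x16_two_degree_blocks_have_four_children(self):
        grid = build_multires_grid(16, 16)
        blocks = grid.level_blocks("2")
        assert len(blocks) == 64
        assert all((b[0].stop - b[0].start) * (b[1].stop - b[1].start) == 4
                   for b in blocks)

    def test_every_cell_has_exactly_one_eight_degree_ancestor(self):
        grid = build_multires_grid(20, 16)
        cover = np.zeros((20, 16), dtype=int)
        for rs, cs in grid.level_blocks("8"):
            cover[rs, cs] += 1
        assert np.all(cover == 1)

    @pytest.mark.parametrize("shape", [(10, 16), (16, 10), (6, 8)])
    def test_indivisible_dimensions_rejected(self, shape):
        with pytest.raises(ValueError):
            build_multires_grid(*shape)


class TestEmissionThreshold:
    def test_top_two_percent_cutoff_by_enumeration(self):
        annual = np.tile(np.arange(1.0, 101.0).reshape(1, 10, 10), (5, 1, 1))
        fld = field_from_annual(annual)
        assert derive_e_min(fld, top_pct=0.02) == pytest.approx(99.0)

    def test_constant_field_returns_that_constant(self):
        fld = field_from_annual(np.full((4, 4, 4), 2.5))
        assert derive_e_min(fld, 0.02) == pytest.approx(2.5)

    def test_all_zero_field_is_undefined(self):
        fld = field_from_annual(np.zeros((4, 4, 4)))
        with pytest.raises(ValueError, match="all-zero"):
            derive_e_min(fld, 0.02)


class TestCriteria:
    CRIT = FCRCriteria(e_min=1.0)

    def test_steady_series_above_threshold_passes(self):
        ok, failed = criteria_pass(np.full(18, 2.0), self.CRIT, e_min=1.0)
        assert ok and not failed

    def test_two_zero_years_of_eighteen_fail_continuity(self):
        series = np.full(18, 5.0)
        series[[3, 10]] = 0.0  # 16/18 = 0.889 < 0.90
        ok, failed = criteria_pass(series, self.CRIT, e_min=1.0)
        assert not ok and failed == {"continuity"}

    def test_small_steady_series_fails_magnitude_only(self):
        ok, failed = criteria_pass(np.full(18, 0.1), self.CRIT, e_min=1.0)
        assert not ok and failed == {"magnitude"}

    def test_spiky_series_fails_variability(self):
        series = np.zeros(18)
        series[0] = 100.0
        ok, failed = criteria_pass(series, self.CRIT, e_min=1.0)
        assert not ok and "variability" in failed


def random_toy_field(seed, n_lat=16, n_lon=16, n_years=10):
    """Annual patterns mixing strong, weak, intermittent and spiky cells."""
    rng = np.random.default_rng(seed)
    base = rng.choice([0.0, 0.05, 0.4, 2.0, 8.0], size=(n_lat, n_lon),
                      p=[0.35, 0.2, 0.2, 0.15, 0.1])
    annual = base[None] * rng.lognormal(0.0, 0.6, size=(n_years, n_lat, n_lon))
    dropout = rng.random((n_years, n_lat, n_lon)) < 0.08
    annual[dropout] = 0.0
    spikes = rng.random((n_lat, n_lon)) < 0.05
    annual[:, spikes] *= rng.random((n_years, spikes.sum())) < 0.15
    mask = gen_country_mask(n_lat, n_lon, rng.integers(1, 4), seed)
    return field_from_annual(annual), mask


class TestDeriveFCRs:
    CRIT = FCRCriteria(e_min=1.0, e_min_8r=0.12)

    def test_all_zero_field_yields_no_regions(self):
        fld = field_from_annual(np.zeros((6, 8, 8)))
        out = derive_fcrs(fld, np.ones((8, 8), int), self.CRIT)
        assert out.n_regions == 0
        assert np.all(out.fcr_id == 0)

    def test_single_steady_cell_becomes_one_level1_region(self):
        annual = np.zeros((6, 8, 8))
        annual[:, 3, 4] = 2.0
        out = derive_fcrs(field_from_annual(annual), np.ones((8, 8), int),
                          FCRCriteria(e_min=1.0, e_min_8r=10.0))
        assert out.n_regions == 1
        assert out.level[1] == "1" and out.cells[1] == [(3, 4)]

    @pytest.mark.parametrize("seed", range(4))
    def test_partition_matches_enumeration_oracle(self, seed):
        fld, mask = random_toy_field(seed)
        got = derive_fcrs(fld, mask, self.CRIT)
        years, _ = fld.annual_sums()
        ids, levels, countries = oracle_fcrs(fld.values, years, mask,
                                             e_min=1.0, e_min_8r=0.12)
        np.testing.assert_array_equal(got.fcr_id, ids)
        assert got.level == levels
        assert got.country == countries

    def test_country_split_keeps_level_label(self):
        annual = np.zeros((6, 8, 8))
        annual[:, 0:2, 2:4] = 0.6  # one aligned 2x2 block across a border
        mask = gen_country_mask(8, 8, 3)  # borders at columns 3 and 5
        out = derive_fcrs(field_from_annual(annual), mask,
                          FCRCriteria(e_min=2.0, e_min_8r=100.0))
        assert out.n_regions == 2
        assert {out.level[i] for i in out.ids} == {"2"}
        assert {out.country[i] for i in out.ids} == {1, 2}

    def test_emission_conservation_over_partition(self):
        fld, mask = random_toy_field(7)
        out = derive_fcrs(fld, mask, self.CRIT)
        series = aggregate_series(fld, None, out)
        assigned_sum = series.emissions.sum(axis=1).values
        low_fire = fld.values[:, out.fcr_id == 0].sum(axis=1)
        np.testing.assert_allclose(assigned_sum + low_fire,
                                   fld.values.sum(axis=(1, 2)), rtol=1e-10)

    def test_raising_threshold_never_adds_level1_regions(self):
        fld, mask = random_toy_field(3)
        counts = []
        for e_min in (0.5, 1.0, 2.0, 4.0):
            out = derive_fcrs(fld, mask, FCRCriteria(e_min=e_min))
            counts.append(sum(1 for lv in out.level.values() if lv == "1"))
        assert counts == sorted(counts, reverse=True)


class TestAggregation:
    def test_two_identical_cells_double_the_series(self):
        annual = np.zeros((6, 8, 8))
        annual[:, 0, 0] = annual[:, 0, 1] = 3.0
        f = field_from_annual(annual)
        out = derive_fcrs(f, np.ones((8, 8), int), FCRCriteria(e_min=5.0))
        assert out.n_regions == 1 and len(out.cells[1]) >= 2
        series = aggregate_series(f, None, out)
        cell = f.values[:, 0, 0]
        np.testing.assert_allclose(series.emissions[1].values, 2 * cell)

    def test_vpd_weighted_mean_hand_computed(self):
        from firecast.io import VPDField
        from firecast.regions import FCRMap

        n = 24
        fld = field_from_annual(np.full((2, 4, 4), 1.0))
        vals = np.zeros((n, 4, 4))
        vals[:, 0, 0], vals[:, 1, 0], vals[:, 2, 0] = 10.0, 20.0, 40.0
        vpd = VPDField(vals, fld.time, lat0=fld.lat0)
        cells = [(0, 0), (1, 0), (2, 0)]
        fmap = FCRMap(np.zeros((4, 4), int), {1: "1"}, {1: 1}, {1: cells})
        w = np.cos(np.deg2rad(fld.lat_centers[[0, 1, 2]]))
        expect = (10 * w[0] + 20 * w[1] + 40 * w[2]) / w.sum()
        series = aggregate_series(fld, vpd, fmap)
        np.testing.assert_allclose(series.vpd[1].values, expect)

    def test_constant_vpd_passes_through(self):
        from firecast.io import VPDField
        from firecast.regions import FCRMap

        fld = field_from_annual(np.full((2, 4, 4), 1.0))
        vpd = VPDField(np.full((24, 4, 4), 7.5), fld.time, lat0=fld.lat0)
        fmap = FCRMap(np.zeros((4, 4), int), {1: "1"}, {1: 1},
                      {1: [(0, 0), (3, 3)]})
        series = aggregate_series(fld, vpd, fmap)
        np.testing.assert_allclose(series.vpd[1].values, 7.5)
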