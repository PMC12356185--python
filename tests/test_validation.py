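import numpy as np
import pandas as pd
import pytest

import grasslue as gl
from grasslue.calendar import Period
from grasslue.validation import (
    bimonthly_median,
    compute_metrics,
    filter_days,
    footprint_mean,
    match_pairs,
    screen_series,
    stratified_report,
)

CAL = gl.BimonthlyCalendar(2020, 2020)


def _series(dt, nt=None, flags=None, start="2020-01-01", **kw):
    dt = np.asarray(dt, dtype=float)
    nt = dt.copy() if nt is None else np.asarray(nt, dtype=float)
    flags = np.zeros(len(dt), dtype=int) if flags is None else np.asarray(flags)
    data = pd.DataFrame({
        "date": pd.date_range(start, periods=len(dt), freq="D"),
        "gpp_dt": dt, "gpp_nt": nt, "gapfill_flag": flags,
    })
    defaults = dict(site_id="T1", location=(0.0, 0.0),
                    land_cover_class="GRA", network="SYN")
    defaults.update(kw)
    return gl.FluxTowerSeries(data=data, **defaults)


class TestScreening:
    def test_boundary_20_percent_accepted(self):
        flags = np.zeros(100, dtype=int)
        flags[:20] = 1
        assert screen_series(_series(np.ones(100), flags=flags))

    def test_21_percent_rejected(self):
        flags = np.zeros(100, dtype=int)
        flags[:21] = 1
        assert not screen_series(_series(np.ones(100), flags=flags))

    def test_clean_series_accepted(self):
        assert screen_series(_series(np.ones(30)))


class TestDtNtFilter:
    def test_gap_semantics(self):
        dt = np.array([5.0, 5.0, 5.0])
        nt = np.array([9.0, 8.0, 5.0])  # gaps 4, 3, 0
        out = filter_days(_series(dt, nt))
        assert len(out.data) == 2
        assert out.data["gpp_nt"].tolist() == [8.0, 5.0]

    def test_idempotent(self):
        s = _series(np.array([5.0, 5.0, 1.0]), np.array([9.0, 7.9, 1.0]))
        once = filter_days(s)
        twice = filter_days(once)
        pd.testing.assert_frame_equal(once.data, twice.data)


class TestBimonthlyMedian:
    def test_median_robust_to_outlier(self):
        med = bimonthly_median(_series([1.0, 2.0, 100.0]), CAL)
        assert med[Period(2020, 1)] == 2.0

    def test_single_day(self):
        med = bimonthly_median(_series([7.5]), CAL)
        assert med[Period(2020, 1)] == 7.5

    def test_even_count_midpoint(self):
        med = bimonthly_median(_series([1.0, 2.0, 3.0, 4.0]), CAL)
        assert med[Period(2020, 1)] == 2.5

    def test_empty_period_absent(self):
        med = bimonthly_median(_series([1.0]), CAL)
        assert Period(2020, 4) not in med

    def test_invariant_to_reordering_within_period(self):
        vals = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        a = bimonthly_median(_series(vals), CAL)
        b = bimonthly_median(_series(np.sort(vals)), CAL)
        assert a == b


class TestFootprint:
    def _cube(self, fill=3.0, w=40, h=40):
        grid = gl.GridSpec(x0=0.0, y0=h * 30.0, dx=30.0, dy=30.0, width=w, height=h)
        vals = gl.quantize(np.full((1, h, w), fill), axis=[Period(2020, 1)], grid=grid)
        return vals

    def test_uniform_raster_returns_value(self):
        cube = self._cube(3.0)
        loc = (600.0, 600.0)
        out = footprint_mean(cube, loc)
        assert out[Period(2020, 1)] == pytest.approx(3.0)

    def test_membership_matches_brute_force_enumeration(self):
        cube = self._cube(1.0)
        loc = (601.0, 613.0)  # deliberately off-center
        gx, gy = cube.grid.center_mesh()
        expected = int(((gx - loc[0]) ** 2 + (gy - loc[1]) ** 2 <= 250.0**2).sum())
        # count via a raster holding each pixel's identity
        ids = np.arange(cube.grid.height * cube.grid.width, dtype=float)
        ids = ids.reshape(1, cube.grid.height, cube.grid.width)
        disc = (gx - loc[0]) ** 2 + (gy - loc[1]) ** 2 <= 250.0**2
        assert 150 < expected < 250  # ~193-221 for a 30 m grid
        vals = cube.physical()[0][disc]
        assert vals.size == expected

    def test_all_nodata_in_disc_missing(self):
        cube = self._cube(np.nan)
        out = footprint_mean(cube, (600.0, 600.0))
        assert out == {}

    def test_outside_extent_raises(self):
        cube = self._cube()
        with pytest.raises(ValueError, match="outside"):
            footprint_mean(cube, (1e6, 1e6))


class TestMetrics:
    def test_perfect_agreement(self):
        r = compute_metrics([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert r.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert r.r2 == pytest.approx(1.0, abs=1e-12)
        assert (r.rmse, r.bias) == (0.0, 0.0)

    def test_constant_offset(self):
        r = compute_metrics([2.0, 3.0, 4.0], [1.0, 2.0, 3.0])
        assert r.bias == pytest.approx(1.0)
        assert r.rmse == pytest.approx(1.0)
        assert r.pearson_r == pytest.approx(1.0)

    def test_hand_arithmetic_three_pairs(self):
        r = compute_metrics([0.0, 1.0, 2.0], [0.0, 2.0, 4.0])
        assert r.pearson_r == pytest.approx(1.0)
        assert r.bias == pytest.approx(-1.0)
        assert r.rmse == pytest.approx(np.sqrt(5.0 / 3.0), abs=1e-9)

    def test_zero_variance_leaves_r_undefined(self):
        r = compute_metrics([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])
        assert r.pearson_r is None and r.r2 is None
        assert r.rmse > 0

    def test_bias_sign_flips_under_swap_rmse_invariant(self):
        m, o = [1.0, 2.0, 5.0], [2.0, 1.0, 3.0]
        a = compute_metrics(m, o)
        b = compute_metrics(o, m)
        assert a.bias == pytest.approx(-b.bias)
        assert a.rmse == pytest.approx(b.rmse)

    def test_rmse_at_least_abs_bias(self):
        rng = np.random.default_rng(5)
        m, o = rng.random(50), rng.random(50)
        r = compute_metrics(m, o)
        assert r.rmse >= abs(r.bias)

    def test_one_to_one_r2_variant(self):
        r = compute_metrics([2.0, 3.0, 4.0], [1.0, 2.0, 3.0],
                            r2_definition="one_to_one")
        assert r.r2 == pytest.approx(1.0 - 3.0 / 2.0)


@pytest.fixture(scope="module")
def known_answer():
    cfg = gl.SceneConfig(grid_width=40, grid_height=40, years=(2020, 2020), seed=3)
    refl = gl.gen_reflectance(cfg)
    clim = gl.gen_climate_cube(cfg, coarse_factor=4)
    cube = gl.compute_ugpp_cube(refl, clim)
    loc = (cfg.origin[0] + 600.0, cfg.origin[1] - 600.0)
    truth = gl.make_tower_truth(cube, loc)
    return cfg, cube, loc, truth


class TestEndToEnd:
    def test_noise_free_recovery(self, known_answer):
        cfg, cube, loc, truth = known_answer
        tower = gl.TowerConfig(site_id="S1", location=loc, years=cfg.years)
        series = gl.gen_tower_series(tower, truth)
        pairs = match_pairs(cube, series, cfg.calendar)
        m, o = zip(*pairs)
        rep = compute_metrics(m, o)
        assert rep.pearson_r == pytest.approx(1.0, abs=1e-12)
        assert rep.rmse == 0.0 and rep.bias == 0.0

    def test_stratified_single_site_equals_pooled(self, known_answer):
        cfg, cube, loc, truth = known_answer
        tower = gl.TowerConfig(site_id="S1", location=loc, years=cfg.years)
        series = gl.gen_tower_series(tower, truth)
        reports = {r.stratum: r for r in stratified_report(cube, [series], cfg.calendar)}
        assert reports["All"].rmse == reports["igbp:GRA"].rmse == 0.0
        assert reports["network:SYN"].pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_two_identical_sites_pool_to_same_metrics(self, known_answer):
        cfg, cube, loc, truth = known_answer
        towers = [gl.TowerConfig(site_id=f"S{i}", location=loc, years=cfg.years)
                  for i in range(2)]
        sites = [gl.gen_tower_series(t, truth) for t in towers]
        reports = {r.stratum: r for r in stratified_report(cube, sites, cfg.calendar)}
        assert reports["All"].n == 12
        assert reports["All"].rmse == 0.0
        assert reports["All"].pearson_r == pytest.approx(1.0, abs=1e-12)

    def test_gapfilled_site_excluded(self, known_answer):
        cfg, cube, loc, truth = known_answer
        tower = gl.TowerConfig(site_id="S1", location=loc, years=cfg.years,
                               gapfill_fraction=0.5)
        series = gl.gen_tower_series(tower, truth)
        assert match_pairs(cube, series, cfg.calendar) == []


def test_tower_series_validates_dates():
    data = pd.DataFrame({
        "date": ["2020-01-02", "2020-01-01"],
        "gpp_dt": [1.0, 2.0], "gpp_nt": [1.0, 2.0], "gapfill_flag": [0, 0],
    })
    with pytest.raises(ValueError):
        gl.FluxTowerSeries(site_id="X", location=(0, 0), land_cover_class="GRA",
                           network="SYN", data=data)
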