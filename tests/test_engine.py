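import numpy as np
import pytest

import grasslue as gl
from grasslue.calendar import Period
from grasslue.cubes import GPP_NODATA, GppCube
from grasslue.engine import STORAGE_STEP, mosaic_tiles, tile_raster


def _grid(w=4, h=4, px=30.0):
    return gl.GridSpec(x0=0.0, y0=h * px, dx=px, dy=px, width=w, height=h)


def _quantized(values, grid=None, scale=STORAGE_STEP, year=2020):
    grid = grid or _grid(*values.shape[::-1][:2])
    periods = [Period(year, k + 1) for k in range(values.shape[0])]
    return gl.quantize(values, axis=periods, grid=grid, scale=scale)


class TestUgpp:
    def test_product(self):
        assert gl.ugpp(np.float64(10), 0.5, 1.0, 1.0) == 5.0

    def test_nodata_propagates(self):
        out = gl.ugpp(np.array([10.0, 10.0]), np.array([0.5, np.nan]),
                      np.array([1.0, 1.0]), np.array([1.0, 1.0]))
        assert out[0] == 5.0 and np.isnan(out[1])

    def test_chained_module_examples(self):
        # par=8.2, fapar(0.495), t_scalar(10), w_scalar(0.2 | max 0.5)
        val = gl.ugpp(
            np.float64(8.2),
            gl.fapar(0.495),
            gl.t_scalar(10.0),
            gl.w_scalar(0.2, gl.LswiContext(np.float64(0.5))),
        )
        assert val == pytest.approx(1.4226, abs=2e-4)

    def test_grid_mismatch_raises(self):
        with pytest.raises(ValueError):
            gl.ugpp(np.zeros((2, 2)), np.zeros((3, 3)), np.zeros((2, 2)), np.zeros((2, 2)))

    def test_monotone_in_par(self):
        rng = np.random.default_rng(2)
        fp, ts, ws = (rng.random((5, 5)) for _ in range(3))
        par = rng.random((5, 5)) * 10
        assert np.all(gl.ugpp(par * 1.5, fp, ts, ws) >= gl.ugpp(par, fp, ts, ws))


class TestQuantize:
    def test_round_half_even(self):
        # 0.25/0.1 = 2.5 exactly in binary -> rounds to the even integer 2
        cube = _quantized(np.array([[[4.26, 0.0, 0.25]]]))
        assert cube.values[0, 0].tolist() == [43, 0, 2]
        assert cube.physical()[0, 0, 0] == pytest.approx(4.3)

    def test_nan_becomes_nodata(self):
        cube = _quantized(np.array([[[np.nan, 1.0]]]))
        assert cube.values[0, 0, 0] == GPP_NODATA
        assert np.isnan(cube.physical()[0, 0, 0])

    def test_negative_clamped_to_zero(self):
        cube = _quantized(np.array([[[-0.4, 1.0]]]))
        assert cube.values[0, 0, 0] == 0

    def test_round_trip_within_half_step(self):
        rng = np.random.default_rng(3)
        vals = rng.random((1, 6, 6)) * 20
        cube = _quantized(vals)
        assert np.max(np.abs(cube.physical() - vals)) <= 0.05 + 1e-12


class TestCalibration:
    def test_grassland_scale_composition(self):
        vals = np.full((1, 4, 4), 5.0)
        cube = _quantized(vals)
        grass = gl.calibrate_grassland(cube, {2020: np.ones((4, 4), dtype=bool)})
        assert grass.scale == pytest.approx(0.086)
        # stored integers copied bit-for-bit inside the mask
        np.testing.assert_array_equal(grass.values, cube.values)
        assert grass.physical()[0, 0, 0] == pytest.approx(50 * 0.086)

    def test_outside_mask_is_nodata(self):
        cube = _quantized(np.full((1, 4, 4), 5.0))
        mask = np.zeros((4, 4), dtype=bool)
        mask[0, 0] = True
        grass = gl.calibrate_grassland(cube, {2020: mask})
        assert grass.values[0, 0, 0] == cube.values[0, 0, 0]
        assert grass.values[0, 1, 1] == GPP_NODATA

    def test_missing_mask_year_names_year(self):
        cube = _quantized(np.full((1, 4, 4), 5.0))
        with pytest.raises(KeyError, match="2020"):
            gl.calibrate_grassland(cube, {2019: np.ones((4, 4), dtype=bool)})

    @pytest.mark.parametrize(
        "value,code,expected",
        [(5.0, "GRA", 4.3), (5.0, "EBF", 6.34), (0.0, "ENF", 0.0)],
    )
    def test_calibrate_by_landcover(self, value, code, expected):
        assert gl.calibrate_by_landcover(value, code) == pytest.approx(expected)

    def test_unknown_class_lists_valid_codes(self):
        with pytest.raises(KeyError, match="GRA"):
            gl.calibrate_by_landcover(5.0, "XYZ")

    def test_shipped_lut_values(self):
        lut = gl.DEFAULT_BIOME_LUT
        assert lut["GRA"] == 0.860
        assert len(lut) == 11
        assert all(v > 0 for v in lut.values())


class TestAnnualize:
    def test_constant_one_gives_365(self):
        cube = _quantized(np.ones((6, 3, 3)))
        annual = gl.annualize(cube)
        assert annual.units == "gC m-2 yr-1"
        np.testing.assert_allclose(annual.physical()[0], 365.0)

    def test_hand_arithmetic_mean(self):
        vals = np.array([0.0, 0.0, 2.0, 4.0, 2.0, 0.0]).reshape(6, 1, 1)
        annual = gl.annualize(_quantized(vals))
        assert annual.physical()[0, 0, 0] == pytest.approx(486.7, abs=0.05)

    def test_single_valid_period(self):
        vals = np.full((6, 1, 1), np.nan)
        vals[2, 0, 0] = 2.0
        annual = gl.annualize(_quantized(vals))
        assert annual.physical()[0, 0, 0] == pytest.approx(730.0)

    def test_no_valid_period_is_nodata(self):
        annual = gl.annualize(_quantized(np.full((6, 1, 1), np.nan)))
        assert annual.values[0, 0, 0] == GPP_NODATA

    def test_multiple_years_rejected(self):
        cube = _quantized(np.ones((1, 2, 2)))
        cube2 = GppCube(axis=[Period(2020, 1), Period(2021, 1)],
                        values=np.zeros((2, 2, 2), dtype=np.uint16),
                        scale=0.1, units="gC m-2 d-1", grid=_grid(2, 2))
        with pytest.raises(ValueError):
            gl.annualize(cube2)


class TestTiling:
    def test_round_trip_bit_exact(self):
        data = np.arange(60 * 60, dtype=np.uint16).reshape(60, 60)
        grid = _grid(60, 60)
        tiles = tile_raster(data, grid, gl.TileScheme(size=900.0))
        assert len(tiles) == 4
        mosaic, mgrid = mosaic_tiles(tiles)
        np.testing.assert_array_equal(mosaic, data)
        assert mgrid == grid

    def test_single_tile_passthrough(self):
        data = np.ones((10, 10), dtype=np.uint16)
        grid = _grid(10, 10)
        tiles = tile_raster(data, grid, gl.TileScheme(size=10 * 30.0))
        assert len(tiles) == 1
        np.testing.assert_array_equal(tiles[0].data, data)

    def test_tile_ids_deterministic(self):
        data = np.zeros((60, 60), dtype=np.uint16)
        grid = _grid(60, 60)
        ids1 = [t.tile_id for t in tile_raster(data, grid, gl.TileScheme(size=900.0))]
        ids2 = [t.tile_id for t in tile_raster(data, grid, gl.TileScheme(size=900.0))]
        assert ids1 == ids2 and len(set(ids1)) == 4

    def test_overlapping_tiles_rejected(self):
        data = np.zeros((10, 10), dtype=np.uint16)
        grid = _grid(10, 10)
        tiles = tile_raster(data, grid, gl.TileScheme(size=10 * 30.0))
        with pytest.raises(ValueError, match="overlap"):
            mosaic_tiles(tiles + tiles)


class TestPipelineInvariants:
    def test_recovery_with_scalars_forced_to_one(self):
        """Zero noise/gaps, optimal LST, saturated LSWI: uGPP equals
        PAR x fAPAR at every pixel to within one quantization step."""
        cfg = gl.SceneConfig(grid_width=24, grid_height=24, years=(2020, 2020), seed=5)
        refl = gl.gen_reflectance(cfg)
        refl.swir1[:] = 0.0  # LSWI = 1 -> W_scalar = 1
        clim = gl.gen_climate_cube(cfg, coarse_factor=4, constant_lst=20.3)
        cube = gl.compute_ugpp_cube(refl, clim)
        expected = clim.par * gl.fapar(gl.ndvi(refl.red, refl.nir))
        assert np.nanmax(np.abs(cube.physical() - expected)) <= 0.1

    def test_increasing_par_never_decreases_gpp(self, pipeline):
        refl, clim, cube = pipeline
        boosted = gl.ClimateCube(periods=clim.periods, lst=clim.lst,
                                 par=clim.par * 1.3, grid=clim.grid)
        cube2 = gl.compute_ugpp_cube(refl, boosted)
        v1, v2 = cube.physical(), cube2.physical()
        ok = ~(np.isnan(v1) | np.isnan(v2))
        assert np.all(v2[ok] >= v1[ok])
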