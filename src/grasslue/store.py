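"""Directory layout for pipeline rasters.

Timestamped inputs are ``<var>_<YYYYMMDD>.tif`` (pre-composite scenes, 8-day
LST, monthly PAR); bimonthly outputs are ``<var>_<YYYY>_p<1..6>.tif``; annual
outputs ``<var>_<YYYY>.tif``; masks ``grassland_<YYYY>.tif``. GPP files carry
``scale_factor`` and ``units`` metadata and nodata 65535.
"""

from __future__ import annotations

import re
from datetime import date, datetime
from pathlib import Path

import numpy as np

from .calendar import BimonthlyCalendar, Period
from .cubes import GPP_NODATA, GppCube, ReflectanceCube, Scene
from .grid import GridSpec, read_geotiff, write_geotiff

_FLOAT_NODATA = -9999.0


def _f2n(arr: np.ndarray) -> np.ndarray:
    out = np.where(np.isnan(arr), _FLOAT_NODATA, arr).astype(np.float32)
    return out


def _n2f(arr: np.ndarray, nodata) -> np.ndarray:
    out = arr.astype(np.float64)
    if nodata is not None:
        out[arr == nodata] = np.nan
    return out


def write_scenes(scenes: list[Scene], outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for s in scenes:
        stamp = s.when.strftime("%Y%m%d")
        for band in ("red", "nir", "swir1"):
            write_geotiff(
                outdir / f"{band}_{stamp}.tif", _f2n(getattr(s, band)), s.grid,
                nodata=_FLOAT_NODATA,
                extra_metadata={"cloud_cover": repr(s.cloud_cover)},
            )


def read_scenes(indir, crs: str = "EPSG:32632") -> list[Scene]:
    indir = Path(indir)
    by_stamp: dict[str, dict[str, tuple]] = {}
    for path in sorted(indir.glob("*_*.tif")):
        m = re.fullmatch(r"(red|nir|swir1)_(\d{8})\.tif", path.name)
        if not m:
            continue
        by_stamp.setdefault(m.group(2), {})[m.group(1)] = read_geotiff(path, crs)
    scenes = []
    for stamp, bands in sorted(by_stamp.items()):
        if set(bands) != {"red", "nir", "swir1"}:
            raise ValueError(f"incomplete band set for scene {stamp}")
        data, grid, meta = bands["red"]
        scenes.append(Scene(
            when=datetime.strptime(stamp, "%Y%m%d").date(),
            red=_n2f(data, meta["nodata"]),
            nir=_n2f(bands["nir"][0], bands["nir"][2]["nodata"]),
            swir1=_n2f(bands["swir1"][0], bands["swir1"][2]["nodata"]),
            cloud_cover=float(meta.get("cloud_cover", 0.0)),
            grid=grid,
        ))
    return scenes


def write_series(series: list[tuple[date, np.ndarray]], var: str, grid: GridSpec, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for when, arr in series:
        write_geotiff(outdir / f"{var}_{when.strftime('%Y%m%d')}.tif",
                      _f2n(arr), grid, nodata=_FLOAT_NODATA)


def read_series(indir, var: str, crs: str = "EPSG:32632"):
    indir = Path(indir)
    series = []
    grid = None
    for path in sorted(indir.glob(f"{var}_*.tif")):
        m = re.fullmatch(rf"{var}_(\d{{8}})\.tif", path.name)
        if not m:
            continue
        data, grid, meta = read_geotiff(path, crs)
        when = datetime.strptime(m.group(1), "%Y%m%d").date()
        series.append((when, _n2f(data, meta["nodata"])))
    if grid is None:
        raise ValueError(f"no {var}_<YYYYMMDD>.tif rasters in {indir}")
    return series, grid


def write_reflectance(cube: ReflectanceCube, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, period in enumerate(cube.periods):
        for band in ("red", "nir", "swir1"):
            write_geotiff(outdir / f"{band}_{period.label()}.tif",
                          _f2n(getattr(cube, band)[i]), cube.grid,
                          nodata=_FLOAT_NODATA)


def read_reflectance(indir, calendar: BimonthlyCalendar, crs: str = "EPSG:32632") -> ReflectanceCube:
    indir = Path(indir)
    grid = None
    bands = {}
    periods = calendar.periods
    for band in ("red", "nir", "swir1"):
        stack = []
        for period in periods:
            path = indir / f"{band}_{period.label()}.tif"
            if not path.exists():
                raise FileNotFoundError(path)
            data, grid, meta = read_geotiff(path, crs)
            stack.append(_n2f(data, meta["nodata"]))
        bands[band] = np.stack(stack)
    return ReflectanceCube(periods=periods, grid=grid, **bands)


def write_gpp(cube: GppCube, outdir, prefix: str = "ugpp") -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for i, label in enumerate(cube.axis):
        name = label.label() if isinstance(label, Period) else str(label)
        write_geotiff(outdir / f"{prefix}_{name}.tif", cube.values[i], cube.grid,
                      nodata=int(GPP_NODATA), scale_factor=cube.scale,
                      units=cube.units)


def read_gpp(indir, prefix: str, calendar: BimonthlyCalendar, crs: str = "EPSG:32632") -> GppCube:
    indir = Path(indir)
    stack, grid, scale, units = [], None, None, None
    periods = calendar.periods
    for period in periods:
        path = indir / f"{prefix}_{period.label()}.tif"
        if not path.exists():
            raise FileNotFoundError(path)
        data, grid, meta = read_geotiff(path, crs)
        stack.append(data.astype(np.uint16))
        scale = meta.get("scale_factor", 0.1)
        units = meta.get("units", "gC m-2 d-1")
    return GppCube(axis=periods, values=np.stack(stack), scale=float(scale),
                   units=str(units), grid=grid)


def write_masks(masks: dict[int, np.ndarray], grid: GridSpec, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for year, mask in masks.items():
        write_geotiff(outdir / f"grassland_{year}.tif",
                      mask.astype(np.uint8), grid)


def read_masks(indir, crs: str = "EPSG:32632") -> dict[int, np.ndarray]:
    indir = Path(indir)
    masks = {}
    for path in sorted(indir.glob("grassland_*.tif")):
        m = re.fullmatch(r"grassland_(\d{4})\.tif", path.name)
        if m:
            data, _, _ = read_geotiff(path, crs)
            masks[int(m.group(1))] = data.astype(bool)
    if not masks:
        raise ValueError(f"no grassland_<YYYY>.tif masks in {indir}")
    return masks
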