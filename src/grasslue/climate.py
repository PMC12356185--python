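"""Temporal compositing to the bimonthly calendar and spatial downscaling.

Coarse drivers (8-day LST, monthly PAR) are averaged into bimonthly means —
each input raster is bucketed by its nominal timestamp (window midpoint for
composites, month midpoint for monthly rasters) into the half-open period
interval — and then interpolated to the 30 m grid with a bicubic spline
evaluated at pixel centers. Pre-composite reflectance scenes are merged per
period by a cloud-cover-weighted average (weight = 1 - cloud_cover,
renormalized over the scenes in which each pixel is clear).
"""

from __future__ import annotations

import logging
from datetime import date, datetime

import numpy as np
from scipy.interpolate import RectBivariateSpline
from scipy.ndimage import distance_transform_edt

from .calendar import BimonthlyCalendar, Period
from .cubes import ClimateCube, ReflectanceCube, Scene
from .grid import GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "bimonthly_mean",
    "composite_reflectance",
    "downscale",
    "gapfill_passthrough",
    "prepare_climate",
]


def _as_date(when) -> date:
    return when.date() if isinstance(when, datetime) else when


def bimonthly_mean(
    series: list[tuple[date, np.ndarray]],
    calendar: BimonthlyCalendar,
) -> dict[Period, np.ndarray]:
    """Unweighted per-pixel mean of timestamped rasters in each bimonthly period.

    Timestamps are nominal (e.g. 8-day window midpoints); membership uses the
    half-open [start, end) period interval. Periods with no inputs yield an
    all-NaN raster and a warning.
    """
    if not series:
        raise ValueError("empty input series")
    shape = series[0][1].shape
    out: dict[Period, np.ndarray] = {}
    for period in calendar:
        members = [arr for when, arr in series if period.contains(_as_date(when))]
        if not members:
            logger.warning("no driver rasters fall in period %s", period.label())
            out[period] = np.full(shape, np.nan)
            continue
        with np.errstate(all="ignore"):
            out[period] = np.nanmean(np.stack(members), axis=0)
    return out


def composite_reflectance(
    scenes: list[Scene],
    calendar: BimonthlyCalendar,
) -> ReflectanceCube:
    """Merge 16-day scenes into bimonthly composites, weighting clearer scenes.

    Each scene carries a cloud_cover fraction; its weight is 1 - cloud_cover,
    renormalized per pixel over the scenes where that pixel is clear. A pixel
    clear in no scene is nodata. If every contributing scene at a clear pixel
    has zero weight (all fully cloudy cloud_cover metadata), the composite
    falls back to the unweighted mean with a warning.
    """
    if not scenes:
        raise ValueError("no scenes to composite")
    grid = scenes[0].grid
    periods = calendar.periods
    nper = len(periods)
    bands = {
        name: np.full((nper, *grid.shape), np.nan) for name in ("red", "nir", "swir1")
    }
    for i, period in enumerate(periods):
        members = [s for s in scenes if period.contains(s.when)]
        if not members:
            continue
        weights = np.array([1.0 - s.cloud_cover for s in members])
        for name in bands:
            stack = np.stack([getattr(s, name) for s in members])
            clear = ~np.isnan(stack)
            w = np.where(clear, weights[:, None, None], 0.0)
            wsum = w.sum(axis=0)
            any_clear = clear.any(axis=0)
            degenerate = any_clear & (wsum == 0)
            if degenerate.any():
                logger.warning(
                    "period %s band %s: %d pixels clear only in zero-weight "
                    "scenes; falling back to unweighted mean",
                    period.label(), name, int(degenerate.sum()),
                )
                w = np.where(degenerate, clear.astype(float), w)
                wsum = w.sum(axis=0)
            with np.errstate(invalid="ignore"):
                comp = np.nansum(np.where(clear, stack, 0.0) * w, axis=0) / wsum
            bands[name][i] = np.where(any_clear, comp, np.nan)
    return ReflectanceCube(periods=periods, grid=grid, **bands)


def _fill_nearest(arr: np.ndarray) -> np.ndarray:
    """Replace NaN cells with the nearest valid cell's value (for spline fits)."""
    mask = np.isnan(arr)
    if not mask.any():
        return arr
    if mask.all():
        raise ValueError("cannot interpolate an all-nodata raster")
    idx = distance_transform_edt(mask, return_distances=False, return_indices=True)
    return arr[tuple(idx)]


def downscale(coarse: np.ndarray, coarse_grid: GridSpec, target_grid: GridSpec) -> np.ndarray:
    """Bicubic-spline interpolation of coarse cell centers onto target pixel centers.

    The spline degree drops automatically when the coarse grid has fewer than
    four cells along an axis (a single cell yields a constant fill). Nodata
    cells are pre-filled from their nearest valid neighbor, and evaluation
    coordinates are clamped to the coarse-center hull, i.e. nearest extension
    beyond the coverage — no extrapolated overshoot at tile edges.
    """
    if coarse.shape != coarse_grid.shape:
        raise ValueError("coarse raster does not match its grid")
    filled = _fill_nearest(np.asarray(coarse, dtype=np.float64))
    h, w = filled.shape
    if h == 1 and w == 1:
        return np.full(target_grid.shape, filled[0, 0])
    # RectBivariateSpline wants ascending axes: use (x, row-flipped y).
    xc = coarse_grid.x_centers()
    yc = coarse_grid.y_centers()[::-1]
    kx = min(3, w - 1)
    ky = min(3, h - 1)
    if h == 1 or w == 1:
        # Degenerate to 1-D interpolation along the long axis.
        from scipy.interpolate import make_interp_spline

        if h == 1:
            coords, vals, k = xc, filled[0, :], kx
            tx = np.clip(target_grid.x_centers(), coords[0], coords[-1])
            line = make_interp_spline(coords, vals, k=max(1, k))(tx)
            return np.tile(line, (target_grid.height, 1))
        coords, vals, k = yc, filled[::-1, 0], ky
        ty = np.clip(target_grid.y_centers()[::-1], coords[0], coords[-1])
        line = make_interp_spline(coords, vals, k=max(1, k))(ty)[::-1]
        return np.tile(line[:, None], (1, target_grid.width))
    spline = RectBivariateSpline(yc, xc, filled[::-1, :], kx=kx, ky=ky)
    # evaluate on ascending axes, then flip rows back to north-up
    ty = np.clip(target_grid.y_centers()[::-1], yc[0], yc[-1])
    tx = np.clip(target_grid.x_centers(), xc[0], xc[-1])
    return spline(ty, tx)[::-1, :]


def gapfill_passthrough(cube: ReflectanceCube) -> ReflectanceCube:
    """Causal same-season gap fill (hook for a full time-series reconstruction).

    A missing pixel in period (year, k) is filled with the most recent valid
    value from the same bimonth-of-year k in an earlier year only — never from
    the future. Gaps with no past same-period value remain nodata.
    """
    new_bands = {}
    for name in ("red", "nir", "swir1"):
        arr = getattr(cube, name).copy()
        # most recent valid same-season value per bimonth index
        last: dict[int, np.ndarray] = {}
        for i in sorted(range(len(cube.periods)), key=lambda j: (cube.periods[j].year, cube.periods[j].index)):
            k = cube.periods[i].index
            if k in last:
                missing = np.isnan(arr[i])
                arr[i] = np.where(missing, last[k], arr[i])
            prev = last.get(k)
            cur = arr[i]
            last[k] = cur.copy() if prev is None else np.where(np.isnan(cur), prev, cur)
        new_bands[name] = arr
    return ReflectanceCube(periods=list(cube.periods), grid=cube.grid, **new_bands)


def prepare_climate(
    lst_series: list[tuple[date, np.ndarray]],
    par_series: list[tuple[date, np.ndarray]],
    coarse_grid: GridSpec,
    target_grid: GridSpec,
    calendar: BimonthlyCalendar,
) -> ClimateCube:
    """Bimonthly-average coarse LST/PAR and downscale both to the target grid.

    Residual negative PAR introduced by interpolation is clamped to 0 (count
    logged); LST passes through unclamped.
    """
    lst_by_period = bimonthly_mean(lst_series, calendar)
    par_by_period = bimonthly_mean(par_series, calendar)
    periods = calendar.periods
    lst = np.full((len(periods), *target_grid.shape), np.nan)
    par = np.full((len(periods), *target_grid.shape), np.nan)
    for i, period in enumerate(periods):
        if not np.isnan(lst_by_period[period]).all():
            lst[i] = downscale(lst_by_period[period], coarse_grid, target_grid)
        if not np.isnan(par_by_period[period]).all():
            p = downscale(par_by_period[period], coarse_grid, target_grid)
            neg = p < 0
            if neg.any():
                logger.info("period %s: clamped %d negative PAR pixels to 0",
                            period.label(), int(neg.sum()))
                p = np.where(neg, 0.0, p)
            par[i] = p
    return ClimateCube(
        periods=periods, lst=lst, par=par, grid=target_grid,
        provenance={
            "lst_native": (coarse_grid.dx, coarse_grid.dy),
            "par_native": (coarse_grid.dx, coarse_grid.dy),
            "downscale": "bicubic spline, nearest edge extension",
        },
    )
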