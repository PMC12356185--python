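"""Eddy-covariance validation protocol: QC, footprint extraction, statistics.

A tower series is accepted only if its gap-filled share is at most 20% of the
full record; surviving days are dropped when the daytime- and nighttime-
partitioned GPP estimates disagree by more than 3 gC m-2 d-1 (strict
inequality: a gap of exactly 3 is kept). Daily DT values are reduced to
bimonthly medians (midpoint convention for even counts), paired with the
model's footprint mean — the unweighted mean over valid pixels whose centers
lie within 250 m of the tower — and scored with Pearson's r, R^2 = r^2, RMSE
and bias (model - observed).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .calendar import BimonthlyCalendar, Period
from .cubes import GppCube
from .engine import calibrate_by_landcover

logger = logging.getLogger(__name__)

MAX_GAPFILL_FRACTION = 0.20
MAX_DTNT_GAP = 3.0       # gC m-2 d-1
FOOTPRINT_RADIUS = 250.0  # meters

__all__ = [
    "FluxTowerSeries",
    "ValidationReport",
    "screen_series",
    "filter_days",
    "bimonthly_median",
    "footprint_mean",
    "compute_metrics",
    "match_pairs",
    "stratified_report",
    "load_tower_csv",
]


@dataclass
class FluxTowerSeries:
    """Daily DT/NT-partitioned GPP for one site, with gap-fill quality flags."""

    site_id: str
    location: tuple[float, float]
    land_cover_class: str
    network: str
    data: pd.DataFrame  # columns: date, gpp_dt, gpp_nt, gapfill_flag

    def __post_init__(self):
        required = {"date", "gpp_dt", "gpp_nt", "gapfill_flag"}
        missing = required - set(self.data.columns)
        if missing:
            raise ValueError(f"tower data missing columns: {sorted(missing)}")
        dates = pd.to_datetime(self.data["date"])
        if not dates.is_monotonic_increasing or dates.duplicated().any():
            raise ValueError("tower dates must be strictly increasing and unique")

    @property
    def gapfill_fraction(self) -> float:
        return float(self.data["gapfill_flag"].mean())


@dataclass
class ValidationReport:
    """Accuracy statistics for matched (model, observed) bimonthly pairs."""

    stratum: str
    n: int
    pearson_r: float | None
    r2: float | None
    rmse: float
    bias: float  # model - observed


def screen_series(series: FluxTowerSeries,
                  max_gapfill: float = MAX_GAPFILL_FRACTION) -> bool:
    """Accept a tower iff its gap-filled share over the full record is <= 20%."""
    if series.data.empty:
        raise ValueError(f"empty series for site {series.site_id}")
    return series.gapfill_fraction <= max_gapfill


def filter_days(series: FluxTowerSeries,
                max_dtnt_gap: float = MAX_DTNT_GAP) -> FluxTowerSeries:
    """Drop days where |GPP_DT - GPP_NT| exceeds 3 gC m-2 d-1 (strictly).

    Idempotent: a second application is a no-op.
    """
    keep = (series.data["gpp_dt"] - series.data["gpp_nt"]).abs() <= max_dtnt_gap
    return replace(series, data=series.data.loc[keep].reset_index(drop=True))


def bimonthly_median(series: FluxTowerSeries,
                     calendar: BimonthlyCalendar) -> dict[Period, float]:
    """Median of surviving daily DT values per bimonthly period.

    Periods with no surviving day are absent from the result. Even counts use
    the midpoint of the two central values.
    """
    dates = pd.to_datetime(series.data["date"])
    out: dict[Period, float] = {}
    for period in calendar:
        sel = (dates >= pd.Timestamp(period.start)) & (dates < pd.Timestamp(period.end))
        vals = series.data.loc[sel.to_numpy(), "gpp_dt"].dropna()
        if len(vals):
            out[period] = float(vals.median())
    return out


def footprint_mean(gpp: GppCube, location: tuple[float, float],
                   radius: float = FOOTPRINT_RADIUS) -> dict:
    """Per-period unweighted mean of valid pixels within the tower footprint.

    Membership is pixel-center-in-circle: a pixel counts iff its center lies
    within ``radius`` of the tower location, distances in the raster's
    projected units. Periods with no valid pixel in the disc are absent.
    """
    x, y = location
    xmin, ymin, xmax, ymax = gpp.grid.extent
    if not (xmin <= x <= xmax and ymin <= y <= ymax):
        raise ValueError(f"tower location {location} outside raster extent {gpp.grid.extent}")
    gx, gy = gpp.grid.center_mesh()
    disc = (gx - x) ** 2 + (gy - y) ** 2 <= radius**2
    if not disc.any():
        return {}
    phys = gpp.physical()
    out = {}
    for i, label in enumerate(gpp.axis):
        vals = phys[i][disc]
        vals = vals[~np.isnan(vals)]
        if vals.size:
            out[label] = float(vals.mean())
    return out


def compute_metrics(model, observed, stratum: str = "All",
                    r2_definition: str = "pearson") -> ValidationReport:
    """Pearson r, R^2, RMSE and bias for matched bimonthly pairs (n >= 2).

    By default R^2 = r^2 (the squared Pearson correlation); pass
    ``r2_definition="one_to_one"`` for 1 - SSres/SStot about the 1:1 line.
    Zero variance in either vector leaves r and R^2 undefined (None) while
    RMSE and bias are still reported.
    """
    m = np.asarray(model, dtype=float)
    o = np.asarray(observed, dtype=float)
    if m.shape != o.shape:
        raise ValueError("model and observed must have equal length")
    if m.size < 2:
        raise ValueError("need at least 2 matched pairs")
    resid = m - o
    rmse = float(np.sqrt(np.mean(resid**2)))
    bias = float(np.mean(resid))
    if np.std(m) == 0 or np.std(o) == 0:
        r = r2 = None
    else:
        r = float(stats.pearsonr(m, o).statistic)
        if r2_definition == "pearson":
            r2 = r * r
        elif r2_definition == "one_to_one":
            sstot = float(np.sum((o - o.mean()) ** 2))
            r2 = 1.0 - float(np.sum(resid**2)) / sstot
        else:
            raise ValueError(f"unknown r2 definition: {r2_definition!r}")
    return ValidationReport(stratum=stratum, n=m.size,
                            pearson_r=r, r2=r2, rmse=rmse, bias=bias)


def match_pairs(
    gpp: GppCube,
    series: FluxTowerSeries,
    calendar: BimonthlyCalendar,
    radius: float = FOOTPRINT_RADIUS,
    lut: dict[str, float] | None = None,
    max_gapfill: float = MAX_GAPFILL_FRACTION,
) -> list[tuple[float, float]]:
    """Full per-site protocol: screen, filter, reduce, extract, pair.

    Model uGPP footprint means are converted to biome-calibrated GPP with the
    site's land-cover class before pairing. Returns [] when the site fails the
    gap-fill screen. A pair exists only when both the footprint mean and the
    tower bimonthly median are present for a period.
    """
    if not screen_series(series, max_gapfill):
        logger.info("site %s rejected: gap-filled fraction %.2f > %.2f",
                    series.site_id, series.gapfill_fraction, max_gapfill)
        return []
    surviving = filter_days(series)
    observed = bimonthly_median(surviving, calendar)
    modeled = footprint_mean(gpp, series.location, radius=radius)
    pairs = []
    for period, obs in observed.items():
        if period in modeled:
            mod = float(calibrate_by_landcover(
                modeled[period], series.land_cover_class, lut))
            pairs.append((mod, obs))
    return pairs


def stratified_report(
    gpp: GppCube,
    sites: list[FluxTowerSeries],
    calendar: BimonthlyCalendar,
    radius: float = FOOTPRINT_RADIUS,
    lut: dict[str, float] | None = None,
) -> list[ValidationReport]:
    """Reports per network and per land-cover class, plus the pooled "All".

    Strata with fewer than two matched pairs are omitted with a log message.
    """
    by_stratum: dict[str, list[tuple[float, float]]] = {"All": []}
    for site in sites:
        pairs = match_pairs(gpp, site, calendar, radius=radius, lut=lut)
        if not pairs:
            continue
        by_stratum["All"].extend(pairs)
        for key in (f"network:{site.network}", f"igbp:{site.land_cover_class}"):
            by_stratum.setdefault(key, []).extend(pairs)
    reports = []
    for stratum, pairs in by_stratum.items():
        if len(pairs) < 2:
            logger.info("stratum %s omitted: %d matched pairs", stratum, len(pairs))
            continue
        model, observed = zip(*pairs)
        reports.append(compute_metrics(model, observed, stratum=stratum))
    return reports


def load_tower_csv(path, *, site_id: str, location: tuple[float, float],
                   land_cover_class: str, network: str = "") -> FluxTowerSeries:
    """Read a daily tower CSV (date,gpp_dt,gpp_nt,gapfill_flag)."""
    data = pd.read_csv(path, parse_dates=["date"])
    return FluxTowerSeries(site_id=site_id, location=location,
                           land_cover_class=land_cover_class,
                           network=network, data=data)
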