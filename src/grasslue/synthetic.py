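"""Synthetic desk-scale inputs with the statistical structure the pipeline assumes.

Every generator is a stand-in shaped by what the downstream stages need, not a
sensor emulator: reflectance follows a per-pixel seasonal sinusoid in NDVI
(summer peak, hemisphere-dependent phase) so composites, indices and the GPP
cycle behave like the real archive; climate drivers are smooth low-frequency
fields with seasonal cycles on their native cadences (8-day LST, monthly PAR);
grassland masks are spatially autocorrelated patches hitting a target areal
fraction; and tower series are a known truth plus independent DT/NT noise with
gap-fill flags. Identical configs (including the seed) give bit-identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import date, timedelta

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter

from .calendar import BimonthlyCalendar
from .climate import composite_reflectance, prepare_climate
from .cubes import DEFAULT_BIOME_LUT, ClimateCube, ReflectanceCube, Scene
from .grid import GridSpec
from .validation import FluxTowerSeries, footprint_mean

__all__ = [
    "SceneConfig",
    "TowerConfig",
    "gen_scenes",
    "gen_reflectance",
    "gen_climate",
    "gen_climate_cube",
    "gen_grassland_mask",
    "gen_tower_series",
    "make_tower_truth",
]

_DAYS_PER_YEAR = 365.25


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry, year range and stochastic settings for all generators."""

    grid_width: int = 64
    grid_height: int = 64
    pixel_size: float = 30.0
    origin: tuple[float, float] = (500000.0, 4500000.0)
    years: tuple[int, int] = (2020, 2020)
    seed: int = 0
    cloud_gap_fraction: float = 0.0
    noise_sd: float = 0.0
    seasonal_amplitude: float = 1.0
    hemisphere: str = "north"
    crs: str = "EPSG:32632"

    def __post_init__(self):
        if self.grid_width < 1 or self.grid_height < 1:
            raise ValueError("grid dimensions must be >= 1")
        if not 0.0 <= self.cloud_gap_fraction <= 1.0:
            raise ValueError("cloud_gap_fraction must be in [0, 1]")
        if self.years[1] < self.years[0]:
            raise ValueError("years must be an inclusive (start, end) range")
        if self.hemisphere not in ("north", "south"):
            raise ValueError("hemisphere must be 'north' or 'south'")

    @property
    def grid(self) -> GridSpec:
        return GridSpec(
            x0=self.origin[0], y0=self.origin[1],
            dx=self.pixel_size, dy=self.pixel_size,
            width=self.grid_width, height=self.grid_height, crs=self.crs,
        )

    @property
    def calendar(self) -> BimonthlyCalendar:
        return BimonthlyCalendar(*self.years)

    @property
    def peak_doy(self) -> float:
        """Day of year of peak greenness: mid-July north, mid-January south."""
        return 196.0 if self.hemisphere == "north" else 15.0


@dataclass(frozen=True)
class TowerConfig:
    """A synthetic eddy-covariance site on (or near) the scene grid."""

    site_id: str
    location: tuple[float, float]
    land_cover_class: str = "GRA"
    years: tuple[int, int] = (2020, 2020)
    gapfill_fraction: float = 0.0
    dtnt_noise_sd: float = 0.0
    seed: int = 0
    network: str = "SYN"

    def __post_init__(self):
        if not 0.0 <= self.gapfill_fraction <= 1.0:
            raise ValueError("gapfill_fraction must be in [0, 1]")
        if self.land_cover_class not in DEFAULT_BIOME_LUT:
            raise ValueError(
                f"unknown land-cover class {self.land_cover_class!r}; "
                f"valid: {sorted(DEFAULT_BIOME_LUT)}"
            )


def _smooth_unit_field(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Spatially autocorrelated field scaled to [-1, 1]."""
    raw = gaussian_filter(rng.standard_normal(shape), sigma=max(1.0, min(shape) / 8))
    peak = np.abs(raw).max()
    return raw / peak if peak > 0 else raw


def _ndvi_fields(config: SceneConfig, rng: np.random.Generator):
    shape = (config.grid_height, config.grid_width)
    mid = 0.47 + 0.08 * _smooth_unit_field(rng, shape)
    amp = config.seasonal_amplitude * (0.35 + 0.03 * _smooth_unit_field(rng, shape))
    return mid, amp


def _bands_for_day(doy: float, config: SceneConfig, mid, amp):
    """Clean red/NIR/SWIR1 for one acquisition date from the NDVI seasonal model."""
    phase = 2.0 * np.pi * (doy - config.peak_doy) / _DAYS_PER_YEAR
    nd = np.clip(mid + amp * np.cos(phase), 0.02, 0.92)
    red = np.full_like(nd, 0.05)
    nir = red * (1.0 + nd) / (1.0 - nd)
    # water index co-varies with greenness: wetter canopies when greener
    lswi_target = 0.5 * nd
    swir1 = nir * (1.0 - lswi_target) / (1.0 + lswi_target)
    return red, nir, swir1


def gen_scenes(config: SceneConfig) -> list[Scene]:
    """Pre-composite 16-day scenes (4 per bimonthly period) with cloud gaps.

    A ``cloud_gap_fraction`` share of pixels per scene is flagged missing
    (NaN in every band); the realized cloudy fraction is recorded as the
    scene's cloud_cover, which drives the compositing weights.
    """
    rng = np.random.default_rng(config.seed)
    mid, amp = _ndvi_fields(config, rng)
    shape = (config.grid_height, config.grid_width)
    scenes: list[Scene] = []
    for period in config.calendar:
        for k in range(4):
            when = period.start + timedelta(days=8 + 16 * k)
            doy = float(when.timetuple().tm_yday)
            red, nir, swir1 = _bands_for_day(doy, config, mid, amp)
            if config.noise_sd > 0:
                red = red + rng.normal(0.0, config.noise_sd, shape)
                nir = nir + rng.normal(0.0, config.noise_sd, shape)
                swir1 = swir1 + rng.normal(0.0, config.noise_sd, shape)
            red, nir, swir1 = (np.clip(b, 0.0, 1.0) for b in (red, nir, swir1))
            if config.cloud_gap_fraction > 0:
                cloudy = rng.random(shape) < config.cloud_gap_fraction
            else:
                cloudy = np.zeros(shape, dtype=bool)
            for b in (red, nir, swir1):
                b[cloudy] = np.nan
            scenes.append(Scene(
                when=when, red=red, nir=nir, swir1=swir1,
                cloud_cover=float(cloudy.mean()), grid=config.grid,
            ))
    return scenes


def gen_reflectance(config: SceneConfig) -> ReflectanceCube:
    """Bimonthly composited reflectance cube (six stacks per year)."""
    return composite_reflectance(gen_scenes(config), config.calendar)


def gen_climate(
    config: SceneConfig,
    coarse_factor: int = 8,
    *,
    lst_mean: float = 12.0,
    lst_amplitude: float = 15.0,
    par_mean: float = 8.0,
    par_amplitude: float = 4.0,
    spatial_sd: float = 1.0,
    constant_lst: float | None = None,
    constant_par: float | None = None,
):
    """Coarse-grid LST (8-day, deg C) and PAR (monthly, MJ m-2 d-1) series.

    Both drivers are seasonal sinusoids peaking in local summer plus a smooth,
    time-invariant spatial anomaly field; the winter LST minimum drops below
    0 degC whenever ``lst_amplitude > lst_mean``. ``constant_lst`` /
    ``constant_par`` replace the corresponding field with a constant
    everywhere (useful for forcing T_scalar = 1). PAR is clipped at 0.

    Returns ``(lst_series, par_series, coarse_grid)`` with each series a list
    of ``(date, array)`` pairs (8-day window midpoints; month midpoints).
    """
    if coarse_factor < 1:
        raise ValueError("coarse_factor must be >= 1")
    rng = np.random.default_rng(config.seed + 1)
    coarse = config.grid.coarsen(coarse_factor)
    shape = coarse.shape
    lst_anom = spatial_sd * _smooth_unit_field(rng, shape)
    par_anom = 0.5 * spatial_sd * _smooth_unit_field(rng, shape)

    def seasonal(doy: float, mean: float, amplitude: float) -> float:
        return mean + amplitude * np.cos(
            2.0 * np.pi * (doy - config.peak_doy) / _DAYS_PER_YEAR
        )

    lst_series = []
    par_series = []
    for year in range(config.years[0], config.years[1] + 1):
        start = date(year, 1, 1)
        n_days = (date(year + 1, 1, 1) - start).days
        for day0 in range(0, n_days, 8):
            mid_date = start + timedelta(days=day0 + 4)
            if mid_date.year != year:
                mid_date = date(year, 12, 31)
            doy = mid_date.timetuple().tm_yday
            if constant_lst is not None:
                arr = np.full(shape, float(constant_lst))
            else:
                arr = seasonal(doy, lst_mean, lst_amplitude) + lst_anom
            lst_series.append((mid_date, arr))
        for month in range(1, 13):
            mid_date = date(year, month, 15)
            doy = mid_date.timetuple().tm_yday
            if constant_par is not None:
                arr = np.full(shape, float(constant_par))
            else:
                arr = np.clip(seasonal(doy, par_mean, par_amplitude) + par_anom, 0.0, None)
            par_series.append((mid_date, arr))
    return lst_series, par_series, coarse


def gen_climate_cube(config: SceneConfig, coarse_factor: int = 8, **kwargs) -> ClimateCube:
    """Full driver preparation: generate, bimonthly-average and downscale."""
    lst_series, par_series, coarse = gen_climate(config, coarse_factor, **kwargs)
    return prepare_climate(lst_series, par_series, coarse, config.grid, config.calendar)


def gen_grassland_mask(config: SceneConfig, fraction: float) -> dict[int, np.ndarray]:
    """Annual binary grassland masks as autocorrelated patches.

    The grassland share equals ``round(fraction * n_pixels) / n_pixels``
    exactly (top quantile of a smooth random field), well within the +-5
    percentage-point contract.
    """
    if not 0.0 <= fraction <= 1.0:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(config.seed + 2)
    shape = (config.grid_height, config.grid_width)
    n = shape[0] * shape[1]
    masks: dict[int, np.ndarray] = {}
    for year in range(config.years[0], config.years[1] + 1):
        if fraction == 0.0:
            masks[year] = np.zeros(shape, dtype=np.uint8)
            continue
        if fraction == 1.0:
            masks[year] = np.ones(shape, dtype=np.uint8)
            continue
        field_ = _smooth_unit_field(rng, shape)
        k = int(round(fraction * n))
        threshold = np.partition(field_.ravel(), n - k)[n - k]
        masks[year] = (field_ >= threshold).astype(np.uint8)
    return masks


def gen_tower_series(
    tower: TowerConfig,
    truth: pd.Series,
    inject_discrepant_days: int | None = None,
) -> FluxTowerSeries:
    """Daily DT/NT GPP around a known truth, with gap-fill flags.

    ``truth`` is a daily series (DatetimeIndex) covering the tower years;
    GPP_DT and GPP_NT each add independent N(0, dtnt_noise_sd^2) noise.
    Exactly ``round(gapfill_fraction * n)`` days are flagged gap-filled.
    When ``inject_discrepant_days`` is given, exactly that many days end up
    with |DT - NT| > 3 gC m-2 d-1 (all other days are clipped to a gap of at
    most 3 so the count is deterministic) — a fixture for the quality filter.
    """
    start = date(tower.years[0], 1, 1)
    end = date(tower.years[1], 12, 31)
    idx = pd.date_range(start, end, freq="D")
    truth = truth.reindex(idx)
    if truth.isna().any():
        raise ValueError("truth series does not cover the configured tower years")
    rng = np.random.default_rng(tower.seed)
    n = len(idx)
    dt = truth.to_numpy(dtype=float) + rng.normal(0.0, tower.dtnt_noise_sd, n)
    nt = truth.to_numpy(dtype=float) + rng.normal(0.0, tower.dtnt_noise_sd, n)
    if inject_discrepant_days is not None:
        k = int(inject_discrepant_days)
        if k > n:
            raise ValueError("cannot inject more discrepant days than days")
        # keep non-injected days safely inside the 3 gC m-2 d-1 gap (the
        # margin guards against fp round-off pushing a clipped gap past 3)
        gap = np.clip(nt - dt, -2.99, 2.99)
        nt = dt + gap
        chosen = rng.choice(n, size=k, replace=False)
        nt[chosen] = dt[chosen] + np.where(rng.random(k) < 0.5, -1.0, 1.0) * (
            3.5 + rng.random(k)
        )
    flags = np.zeros(n, dtype=np.uint8)
    n_gap = int(round(tower.gapfill_fraction * n))
    if n_gap:
        flags[rng.choice(n, size=n_gap, replace=False)] = 1
    data = pd.DataFrame(
        {"date": idx, "gpp_dt": dt, "gpp_nt": nt, "gapfill_flag": flags}
    )
    return FluxTowerSeries(
        site_id=tower.site_id,
        location=tower.location,
        land_cover_class=tower.land_cover_class,
        network=tower.network,
        data=data,
    )


def make_tower_truth(
    gpp_cube,
    location: tuple[float, float],
    radius: float = 250.0,
    land_cover_class: str = "GRA",
    lut: dict[str, float] | None = None,
) -> pd.Series:
    """Known-answer daily truth: the model's footprint mean, constant per period.

    A tower measures actual GPP, so the uGPP footprint mean is converted with
    the site's biome eps_LUEmax before use as truth. Running the forward model
    at the tower and reading back its own (calibrated) footprint mean
    guarantees the validation chain recovers r = 1, RMSE = 0, bias = 0 under
    zero noise.
    """
    from .engine import calibrate_by_landcover

    per_period = footprint_mean(gpp_cube, location, radius=radius)
    per_period = {
        p: float(calibrate_by_landcover(v, land_cover_class, lut))
        for p, v in per_period.items()
    }
    chunks = []
    for period, value in per_period.items():
        days = pd.date_range(period.start, period.end - timedelta(days=1), freq="D")
        chunks.append(pd.Series(value, index=days))
    return pd.concat(chunks).sort_index()
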