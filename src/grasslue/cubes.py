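"""In-memory containers for the pipeline's raster stacks and the biome lookup.

Float rasters use NaN as the nodata sentinel throughout; quantized GPP stacks
store unsigned 16-bit integers with nodata 65535 and a metadata scale factor,
mirroring the COG convention of the published product (physical value =
stored integer x scale, exactly).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from datetime import date

import numpy as np

from .calendar import Period
from .grid import GridSpec

GPP_NODATA = np.uint16(65535)

#: MOD17 biome-property lookup: IGBP class code -> epsilon_LUEmax
#: in gC m-2 d-1 MJ-1.
DEFAULT_BIOME_LUT: dict[str, float] = {
    "ENF": 0.962,
    "EBF": 1.268,
    "DNF": 1.086,
    "DBF": 1.165,
    "MF": 1.051,
    "CSH": 1.281,
    "OSH": 0.841,
    "WSA": 1.239,
    "SAV": 1.206,
    "GRA": 0.860,
    "CRO": 1.044,
}

_CLASS_NAMES = {
    "ENF": "Evergreen Needleleaf Forests",
    "EBF": "Evergreen Broadleaf Forests",
    "DNF": "Deciduous Needleleaf Forests",
    "DBF": "Deciduous Broadleaf Forests",
    "MF": "Mixed Forests",
    "CSH": "Closed Shrublands",
    "OSH": "Open Shrublands",
    "WSA": "Woody Savannas",
    "SAV": "Savannas",
    "GRA": "Grasslands",
    "CRO": "Croplands",
}


def load_biome_lut(path) -> dict[str, float]:
    """Read a ``class_code,class_name,eps_luemax`` CSV into a lookup dict."""
    lut: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            lut[row["class_code"].strip()] = float(row["eps_luemax"])
    if not lut:
        raise ValueError(f"empty biome lookup table: {path}")
    return lut


def save_biome_lut(path, lut: dict[str, float] | None = None) -> None:
    lut = DEFAULT_BIOME_LUT if lut is None else lut
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_code", "class_name", "eps_luemax"])
        for code, eps in lut.items():
            w.writerow([code, _CLASS_NAMES.get(code, code), eps])


@dataclass
class Scene:
    """One pre-composite (16-day cadence) reflectance acquisition.

    Bands are float arrays with NaN where the pixel was cloud-masked;
    ``cloud_cover`` is the scene-level cloudy fraction used as the
    compositing weight (w = 1 - cloud_cover).
    """

    when: date
    red: np.ndarray
    nir: np.ndarray
    swir1: np.ndarray
    cloud_cover: float
    grid: GridSpec

    def __post_init__(self):
        if not (self.red.shape == self.nir.shape == self.swir1.shape == self.grid.shape):
            raise ValueError("scene bands must share the grid shape")
        if not 0.0 <= self.cloud_cover <= 1.0:
            raise ValueError("cloud_cover must be in [0, 1]")


@dataclass
class ReflectanceCube:
    """Bimonthly red/NIR/SWIR1 stacks on a common grid.

    Arrays are shaped ``(n_periods, height, width)`` with NaN nodata; a pixel
    missing in any band is treated as missing in every derived index.
    """

    periods: list[Period]
    red: np.ndarray
    nir: np.ndarray
    swir1: np.ndarray
    grid: GridSpec

    def __post_init__(self):
        n = len(self.periods)
        for name in ("red", "nir", "swir1"):
            arr = getattr(self, name)
            if arr.shape != (n, *self.grid.shape):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, *{self.grid.shape})")

    @property
    def n_periods(self) -> int:
        return len(self.periods)

    def joint_valid(self) -> np.ndarray:
        """Boolean stack: pixel valid in all three bands."""
        return ~(np.isnan(self.red) | np.isnan(self.nir) | np.isnan(self.swir1))

    def period_index(self, period: Period) -> int:
        return self.periods.index(period)


@dataclass
class ClimateCube:
    """Bimonthly LST (deg C) and PAR (MJ m-2 d-1) drivers on the 30 m grid."""

    periods: list[Period]
    lst: np.ndarray
    par: np.ndarray
    grid: GridSpec
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        n = len(self.periods)
        for name in ("lst", "par"):
            arr = getattr(self, name)
            if arr.shape != (n, *self.grid.shape):
                raise ValueError(f"{name} shape {arr.shape} != ({n}, *{self.grid.shape})")


@dataclass
class GppCube:
    """Integer-quantized GPP with a metadata scale factor.

    ``values`` is uint16 with nodata 65535; the physical value is
    ``stored * scale`` (scale 0.1 for uGPP, 0.1 x 0.86 = 0.086 for the
    grassland-calibrated product). ``axis`` labels the leading dimension:
    bimonthly periods or years.
    """

    axis: list  # list[Period] (bimonthly) or list[int] (annual)
    values: np.ndarray
    scale: float
    units: str
    grid: GridSpec

    def __post_init__(self):
        if self.values.dtype != np.uint16:
            raise TypeError("GppCube stores uint16 integers")
        if self.values.shape != (len(self.axis), *self.grid.shape):
            raise ValueError("values shape does not match axis/grid")
        if self.scale <= 0:
            raise ValueError("scale must be positive")

    @property
    def nodata(self) -> int:
        return int(GPP_NODATA)

    def physical(self) -> np.ndarray:
        """Dequantized float stack (NaN at nodata)."""
        out = self.values.astype(np.float64) * self.scale
        out[self.values == GPP_NODATA] = np.nan
        return out

    def valid(self) -> np.ndarray:
        return self.values != GPP_NODATA
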