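"""Spectral indices: NDVI, LSWI and the fAPAR stretch.

NDVI = (NIR - red) / (NIR + red), LSWI = (NIR - SWIR1) / (NIR + SWIR1).
fAPAR is the standard linear stretch of NDVI between fixed thresholds:

    fAPAR = (NDVI - NDVI_min) * (fAPAR_max - fAPAR_min)
            / (NDVI_max - NDVI_min) + fAPAR_min

with NDVI_min/max = 0.03/0.96 (the 2%/98% points of the global NDVI
distribution) and fAPAR_min/max = 0.001/0.95 (theoretical bounds for all
vegetation). Outside the stretch the output is clamped to the bounds.

Nodata handling: NaN propagates; a zero denominator in a normalized
difference yields NaN.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["FaparParams", "ndvi", "lswi", "fapar"]


@dataclass(frozen=True)
class FaparParams:
    ndvi_min: float = 0.03
    ndvi_max: float = 0.96
    fapar_min: float = 0.001
    fapar_max: float = 0.95

    def __post_init__(self):
        if not self.ndvi_min < self.ndvi_max:
            raise ValueError("ndvi_min must be < ndvi_max")
        if not self.fapar_min < self.fapar_max:
            raise ValueError("fapar_min must be < fapar_max")


def _normalized_difference(a, b):
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"band shapes differ: {a.shape} vs {b.shape}")
    denom = a + b
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(denom == 0, np.nan, (a - b) / denom)
    return out


def ndvi(red, nir):
    """Normalized difference vegetation index (NIR - red)/(NIR + red)."""
    return _normalized_difference(nir, red)


def lswi(nir, swir1):
    """Land surface water index (NIR - SWIR1)/(NIR + SWIR1)."""
    return _normalized_difference(nir, swir1)


def fapar(ndvi_values, params: FaparParams = FaparParams()):
    """Fraction of absorbed PAR from NDVI via the linear stretch, clamped."""
    nd = np.asarray(ndvi_values, dtype=np.float64)
    slope = (params.fapar_max - params.fapar_min) / (params.ndvi_max - params.ndvi_min)
    out = (nd - params.ndvi_min) * slope + params.fapar_min
    return np.clip(out, params.fapar_min, params.fapar_max)
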