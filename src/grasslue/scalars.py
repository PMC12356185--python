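"""Environmental down-regulation of light-use efficiency.

The effective LUE is eps_LUE = eps_LUEmax * T_scalar * W_scalar.

T_scalar follows the quadratic temperature-response used across the
LUE/VPM model family,

    T_scalar = (T - T_max)(T - T_min) / [(T - T_max)(T - T_min) - (T - T_opt)^2]

with T_min = 0.0, T_max = 48.0 and T_opt = 20.3 degrees Celsius. At or below
0 degC the scalar is set to 0 exactly (frozen canopies do not photosynthesize
in this model), and at or above T_max it is likewise 0: the raw formula is 0
at T_max and the quadratic rationale does not extend beyond it, so 0 is the
continuous extension. Any in-range negative value is clamped to 0.

W_scalar encodes water stress from the land surface water index:

    W_scalar = 1 - (1 - LSWI) / (1 + LSWI_max)

where LSWI_max is the per-pixel maximum LSWI over a configurable window
(default: the calendar year, the convention of the VPM family). The more
common VPM variant (1 + LSWI)/(1 + LSWI_max) is available behind
``formula="vpm"`` for sensitivity checks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

__all__ = ["TempParams", "LswiContext", "t_scalar", "lswi_max", "w_scalar", "eps_lue"]


@dataclass(frozen=True)
class TempParams:
    """Minimum, maximum and optimal photosynthesis temperatures (deg C)."""

    t_min: float = 0.0
    t_max: float = 48.0
    t_opt: float = 20.3

    def __post_init__(self):
        if not self.t_min < self.t_opt < self.t_max:
            raise ValueError("require t_min < t_opt < t_max")


@dataclass(frozen=True)
class LswiContext:
    """Per-pixel maximum LSWI over the stress-normalization window."""

    lswi_max: np.ndarray
    window: str = "annual"


def t_scalar(t, params: TempParams = TempParams()):
    """Temperature scalar in [0, 1]; 0 at or below freezing and at or above t_max."""
    t = np.asarray(t, dtype=np.float64)
    num = (t - params.t_max) * (t - params.t_min)
    den = num - (t - params.t_opt) ** 2
    with np.errstate(divide="ignore", invalid="ignore"):
        out = np.where(den == 0, np.nan, num / den)
    out = np.where((t <= params.t_min) | (t >= params.t_max), 0.0, out)
    out = np.clip(out, 0.0, 1.0)
    return np.where(np.isfinite(t), out, np.nan)


def lswi_max(lswi_series: np.ndarray, window: str = "annual") -> LswiContext:
    """Per-pixel maximum of an LSWI stack, ignoring NaN.

    ``lswi_series`` is shaped (n_periods, ...); pixels with no valid
    observation in the window become NaN.
    """
    series = np.asarray(lswi_series, dtype=np.float64)
    if series.ndim < 1 or series.shape[0] == 0:
        raise ValueError("lswi_series must have at least one layer")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN pixels -> NaN
        mx = np.nanmax(series, axis=0)
    return LswiContext(lswi_max=mx, window=window)


def w_scalar(lswi_values, ctx: LswiContext, formula: str = "printed"):
    """Water scalar in [0, 1].

    ``formula="printed"`` is 1 - (1 - LSWI)/(1 + LSWI_max); ``"vpm"`` is
    (1 + LSWI)/(1 + LSWI_max). Pixels where 1 + LSWI_max <= 0 are nodata.
    """
    lswi_values = np.asarray(lswi_values, dtype=np.float64)
    denom = 1.0 + np.asarray(ctx.lswi_max, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        if formula == "printed":
            out = 1.0 - (1.0 - lswi_values) / denom
        elif formula == "vpm":
            out = (1.0 + lswi_values) / denom
        else:
            raise ValueError(f"unknown w_scalar formula: {formula!r}")
    out = np.where(denom <= 0, np.nan, out)
    return np.clip(out, 0.0, 1.0)


def eps_lue(eps_max, ts, ws):
    """Effective light-use efficiency eps_max * T_scalar * W_scalar."""
    if np.any(np.asarray(eps_max) <= 0):
        raise ValueError("eps_max must be positive")
    return np.asarray(eps_max, dtype=np.float64) * ts * ws
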