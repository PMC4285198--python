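"""Transient thermal dissipation (TTD) sap-flow processing.

The TTD method uses a Granier-style probe pair on a cyclic heating schedule
(10 min heating, 20 min cooling). The temperature signal of a cycle is

    dT_a = dT_on - dT_off

with dT_off interpolated in time to the end of heating. The transient index

    Ka = (dT_0a - dT_ua) / dT_ua

compares the measured signal dT_ua against the nightly zero-flow maximum
dT_0a, and converts to hourly sap flux density through the
non-species-specific calibration Js = 12.95 x Ka x 10^2 (kg m-2 sapwood h-1).
Daily totals scale to stand transpiration through the sapwood-to-ground area
ratio and a radial-profile reduction coefficient.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .constants import (
    DEFAULT_RADIAL_COEFF,
    DEFAULT_ROW_SPACING_M,
    DEFAULT_SAPWOOD_AREA_M2,
    TTD_CALIBRATION_KG_M2_H,
)

__all__ = [
    "StandParams",
    "transient_index",
    "hourly_flux",
    "nightly_zero_flow",
    "interpolate_dt_off",
    "stand_transpiration",
    "daily_transpiration",
]


@dataclass(frozen=True)
class StandParams:
    """Tree-to-stand scaling constants."""

    sapwood_area_m2: float = DEFAULT_SAPWOOD_AREA_M2
    spacing_m: tuple[float, float] = DEFAULT_ROW_SPACING_M
    radial_coeff: float = DEFAULT_RADIAL_COEFF

    def __post_init__(self) -> None:
        if self.spacing_area_m2 <= 0:
            raise ValueError("spacing area must be positive")
        if not 0.0 < self.radial_coeff <= 1.0:
            raise ValueError("radial coefficient must be in (0, 1]")
        if self.sapwood_area_m2 <= 0:
            raise ValueError("sapwood area must be positive")

    @property
    def spacing_area_m2(self) -> float:
        """Ground area per tree, m2."""
        return self.spacing_m[0] * self.spacing_m[1]

    @property
    def density_trees_ha(self) -> float:
        """Planting density, trees per hectare (1e4 m2 / spacing area)."""
        return 1.0e4 / self.spacing_area_m2


def transient_index(dt_a, dt_0a, *, return_n_floored: bool = False):
    """Transient thermal index Ka = (dT_0a - dT_a) / dT_a.

    Negative values (measured signal above the zero-flow maximum, e.g.
    nighttime noise) are floored at 0; the floored count is available via
    ``return_n_floored``. Non-positive temperature signals are rejected.
    """
    dt_a = np.asarray(dt_a, dtype=float)
    dt_0a = np.asarray(dt_0a, dtype=float)
    valid = ~(np.isnan(dt_a) | np.isnan(dt_0a))
    if np.any((dt_a[valid] <= 0) | (dt_0a[valid] <= 0)):
        raise ValueError("temperature signals must be positive")
    ka = (dt_0a - dt_a) / dt_a
    n_floored = int(np.sum(ka[valid] < 0))
    ka = np.maximum(ka, 0.0)
    ka = ka if ka.ndim else float(ka)
    if return_n_floored:
        return ka, n_floored
    return ka


def hourly_flux(ka):
    """Hourly sap flux density Js (kg m-2 sapwood h-1) from Ka."""
    ka = np.asarray(ka, dtype=float)
    if np.any(ka[~np.isnan(ka)] < 0):
        raise ValueError("Ka must be non-negative (floor applied upstream)")
    js = TTD_CALIBRATION_KG_M2_H * ka
    return js if js.ndim else float(js)


def nightly_zero_flow(dt_a: pd.Series, *, window=("03:00", "06:00"),
                      drift_threshold: float = 0.05) -> pd.DataFrame:
    """Per-night zero-flow signal dT_0a, carried forward across the day.

    ``dt_a`` is a timestamped series of cycle signals. The zero-flow maximum
    is the window maximum in the pre-dawn hours (default 03:00-06:00) and is
    attributed to the calendar day that starts that morning. A missing night
    reuses the previous night's value (flagged); night-to-night relative
    changes above ``drift_threshold`` are flagged as drift.

    Returns a date-indexed frame with columns dt_0a, reused, drift.
    """
    s = dt_a.sort_index()
    night = s.between_time(*window, inclusive="left")
    per_day = night.groupby(night.index.normalize()).max()
    days = pd.date_range(s.index[0].normalize(), s.index[-1].normalize(), freq="D")
    out = per_day.reindex(days)
    reused = out.isna() & (days != days[0])
    out = out.ffill()
    prev = out.shift(1)
    with np.errstate(invalid="ignore", divide="ignore"):
        drift = (out - prev).abs() / prev > drift_threshold
    n_drift = int(drift.fillna(False).sum())
    if n_drift:
        warnings.warn(
            f"{n_drift} night(s) with zero-flow drift > {drift_threshold:.0%}",
            stacklevel=2)
    return pd.DataFrame({
        "dt_0a": out,
        "reused": reused.fillna(False),
        "drift": drift.fillna(False),
    }, index=pd.DatetimeIndex(days, name="date"))


def interpolate_dt_off(dt_off: pd.Series, at: pd.DatetimeIndex) -> pd.Series:
    """dT_off linearly interpolated in time to the heating-end instants.

    Target instants outside the span of surrounding cooling-phase
    measurements (isolated records) are rejected (NaN).
    """
    s = dt_off.dropna().sort_index()
    if s.empty:
        raise ValueError("no cooling-phase measurements to interpolate")
    t_obs = s.index.view("int64").astype(float)
    t_new = pd.DatetimeIndex(at).view("int64").astype(float)
    vals = np.interp(t_new, t_obs, s.to_numpy(), left=np.nan, right=np.nan)
    return pd.Series(vals, index=at, name="dt_off")


def stand_transpiration(jout_day, stand: StandParams = StandParams()):
    """Stand transpiration (mm d-1) from daily sap flux density.

    T = radial_coeff * Jout_day * (sapwood area / ground area per tree).
    With Jout_day in kg m-2 sapwood d-1 the result, in kg per m2 ground per
    day, is numerically mm d-1.
    """
    jout = np.asarray(jout_day, dtype=float)
    if np.any(jout[~np.isnan(jout)] < 0):
        raise ValueError("daily flux must be non-negative")
    t = stand.radial_coeff * jout * (stand.sapwood_area_m2 / stand.spacing_area_m2)
    return t if t.ndim else float(t)


def daily_transpiration(ka: pd.Series, stand: StandParams = StandParams(),
                        cycles_per_hour: int = 2) -> pd.DataFrame:
    """Daily stand transpiration from a timestamped Ka series.

    Per-cycle Ka values are averaged to hourly flux densities, accumulated
    over 24 h to Jout_day (kg m-2 d-1), then scaled to the stand. Cycles
    default to the 10-min-heating / 20-min-cooling schedule (2 per hour).
    """
    js_cycle = hourly_flux(ka.to_numpy())
    s = pd.Series(js_cycle, index=ka.index)
    hourly = s.groupby([s.index.normalize(), s.index.hour]).mean()
    jout = hourly.groupby(level=0).sum()
    t = stand_transpiration(jout.to_numpy(), stand)
    return pd.DataFrame({"jout_day": jout.to_numpy(), "t_mea": t},
                        index=pd.DatetimeIndex(jout.index.get_level_values(0),
                                               name="date"))
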