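"""Weather ingestion and reference evapotranspiration.

Converts (half-hourly or daily) weather records into the daily drivers of the
transpiration model: FAO-56 Penman-Monteith reference evapotranspiration
(ET0, mm d-1) for the 0.12 m grass reference surface, and the daily maximum
vapour pressure deficit (VPDmax, kPa).

Gaps are propagated as NaN with an explicit completeness flag; nothing is
imputed here.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .constants import (
    REFERENCE_ALBEDO,
    SOLAR_CONSTANT_MJ_M2_MIN,
    STEFAN_BOLTZMANN_MJ_K4_M2_DAY,
    Site,
)

__all__ = [
    "saturation_vapor_pressure",
    "vpd",
    "extraterrestrial_radiation",
    "clear_sky_radiation",
    "net_radiation",
    "daily_et0",
    "aggregate_halfhourly_to_daily",
    "read_weather_csv",
    "et0_from_daily_frame",
]

_T_MIN, _T_MAX = -20.0, 60.0


def saturation_vapor_pressure(tair):
    """Saturation vapour pressure (kPa) from the Tetens form.

    es = 0.6108 * exp(17.27 T / (T + 237.3)), T in deg C.
    """
    t = np.asarray(tair, dtype=float)
    if np.any((t <= _T_MIN) | (t >= _T_MAX)):
        raise ValueError(f"air temperature outside ({_T_MIN}, {_T_MAX}) degC")
    es = 0.6108 * np.exp(17.27 * t / (t + 237.3))
    return es if es.ndim else float(es)


def vpd(tair, rh):
    """Vapour pressure deficit (kPa) from temperature (degC) and RH (%)."""
    rh_arr = np.asarray(rh, dtype=float)
    if np.any((rh_arr < 0.0) | (rh_arr > 100.0)):
        raise ValueError("relative humidity must be within [0, 100] %")
    out = saturation_vapor_pressure(tair) * (1.0 - rh_arr / 100.0)
    return out if np.ndim(out) else float(out)


def _slope_svp(tmean):
    """Slope of the saturation vapour pressure curve, kPa degC-1."""
    return 4098.0 * saturation_vapor_pressure(tmean) / (tmean + 237.3) ** 2


def _psychrometric_constant(elevation_m):
    """gamma (kPa degC-1) from barometric pressure at station elevation."""
    pressure = 101.3 * ((293.0 - 0.0065 * elevation_m) / 293.0) ** 5.26
    return 0.665e-3 * pressure


def extraterrestrial_radiation(latitude_deg, doy):
    """Daily extraterrestrial radiation Ra, MJ m-2 d-1."""
    lat = np.radians(latitude_deg)
    doy = np.asarray(doy, dtype=float)
    dr = 1.0 + 0.033 * np.cos(2.0 * np.pi * doy / 365.0)
    decl = 0.409 * np.sin(2.0 * np.pi * doy / 365.0 - 1.39)
    x = np.clip(-np.tan(lat) * np.tan(decl), -1.0, 1.0)
    ws = np.arccos(x)
    ra = (24.0 * 60.0 / np.pi) * SOLAR_CONSTANT_MJ_M2_MIN * dr * (
        ws * np.sin(lat) * np.sin(decl) + np.cos(lat) * np.cos(decl) * np.sin(ws)
    )
    return ra if np.ndim(ra) else float(ra)


def clear_sky_radiation(latitude_deg, doy, elevation_m):
    """Clear-sky shortwave radiation Rso, MJ m-2 d-1."""
    return (0.75 + 2.0e-5 * elevation_m) * extraterrestrial_radiation(latitude_deg, doy)


def net_radiation(tmin, tmax, ea, rs, doy, site: Site):
    """Daily net radiation (MJ m-2 d-1) from measured shortwave radiation.

    Net shortwave with the reference albedo minus net longwave with the
    FAO-56 cloudiness and humidity corrections.
    """
    rs = np.asarray(rs, dtype=float)
    rns = (1.0 - site.albedo) * rs
    rso = clear_sky_radiation(site.latitude_deg, doy, site.elevation_m)
    with np.errstate(divide="ignore", invalid="ignore"):
        rel = np.where(rso > 0, rs / rso, 0.0)
    cloud = 1.35 * np.clip(rel, 0.0, 1.0) - 0.35
    tk4 = ((np.asarray(tmax, float) + 273.16) ** 4 + (np.asarray(tmin, float) + 273.16) ** 4) / 2.0
    rnl = STEFAN_BOLTZMANN_MJ_K4_M2_DAY * tk4 * (0.34 - 0.14 * np.sqrt(np.maximum(ea, 0.0))) * cloud
    rn = rns - rnl
    return rn if np.ndim(rn) else float(rn)


def daily_et0(tmin, tmax, rh_mean, rs, u2, doy, site: Site = Site(),
              ea=None, rn=None, g=0.0):
    """FAO-56 daily Penman-Monteith reference evapotranspiration, mm d-1.

    Parameters
    ----------
    tmin, tmax : daily temperature extremes, degC.
    rh_mean : daily mean relative humidity, %; used for the actual vapour
        pressure ``ea = RHmean/100 * (es(Tmax)+es(Tmin))/2`` unless ``ea``
        (kPa) is given directly.
    rs : measured incoming shortwave radiation, MJ m-2 d-1.
    u2 : wind speed at 2 m, m s-1.
    doy : day of year (for extraterrestrial radiation).
    rn : net radiation override, MJ m-2 d-1; computed from ``rs`` if None.
    g : soil heat flux, MJ m-2 d-1 (0 for daily steps).

    Missing drivers (NaN) yield NaN, never a silent zero.
    """
    tmin = np.asarray(tmin, float)
    tmax = np.asarray(tmax, float)
    tmean = (tmin + tmax) / 2.0
    es = (saturation_vapor_pressure(tmax) + saturation_vapor_pressure(tmin)) / 2.0
    if ea is None:
        rh_arr = np.asarray(rh_mean, dtype=float)
        valid = ~np.isnan(rh_arr)
        if np.any((rh_arr[valid] < 0.0) | (rh_arr[valid] > 100.0)):
            raise ValueError("relative humidity must be within [0, 100] %")
        ea = rh_arr / 100.0 * es
    ea = np.asarray(ea, dtype=float)
    if rn is None:
        rn = net_radiation(tmin, tmax, ea, rs, doy, site)
    rn = np.asarray(rn, dtype=float)
    delta = _slope_svp(tmean)
    gamma = _psychrometric_constant(site.elevation_m)
    u2 = np.asarray(u2, dtype=float)
    num = 0.408 * delta * (rn - g) + gamma * 900.0 / (tmean + 273.0) * u2 * (es - ea)
    den = delta + gamma * (1.0 + 0.34 * u2)
    et0 = np.maximum(num / den, 0.0)
    # NaN drivers must surface as NaN (maximum propagates them already)
    return et0 if et0.ndim else float(et0)


def aggregate_halfhourly_to_daily(records: pd.DataFrame,
                                  min_completeness: float = 0.8,
                                  expected_per_day: int = 48) -> pd.DataFrame:
    """Aggregate sub-daily weather records to daily drivers.

    ``records`` needs a DatetimeIndex (or a ``timestamp`` column) and columns
    ``tair`` (degC), ``rh`` (%), ``rs`` (MJ m-2 per interval), ``u2`` (m s-1),
    ``p`` (mm per interval). Sums P and Rs, takes mean/extremes of T and RH,
    and VPDmax as the maximum per-interval VPD. Days with fewer than
    ``min_completeness * expected_per_day`` intervals are marked incomplete
    and their aggregates set to NaN.
    """
    df = records.copy()
    if "timestamp" in df.columns:
        df = df.set_index(pd.DatetimeIndex(pd.to_datetime(df["timestamp"])))
    if not isinstance(df.index, pd.DatetimeIndex):
        raise TypeError("records need a DatetimeIndex or a 'timestamp' column")
    if not df.index.is_monotonic_increasing:
        raise ValueError("timestamps must be increasing")
    df["vpd"] = vpd(df["tair"].to_numpy(), df["rh"].to_numpy())
    grp = df.groupby(df.index.normalize())
    daily = pd.DataFrame({
        "tmean": grp["tair"].mean(),
        "tmin": grp["tair"].min(),
        "tmax": grp["tair"].max(),
        "rh_mean": grp["rh"].mean(),
        "rs": grp["rs"].sum(),
        "u2": grp["u2"].mean(),
        "p": grp["p"].sum(),
        "vpd_max": grp["vpd"].max(),
        "n_intervals": grp["tair"].count(),
    })
    daily["complete"] = daily["n_intervals"] >= min_completeness * expected_per_day
    cols = ["tmean", "tmin", "tmax", "rh_mean", "rs", "u2", "p", "vpd_max"]
    daily.loc[~daily["complete"], cols] = np.nan
    daily.index.name = "date"
    return daily


def vpdmax_from_extremes(tmax, rh_min):
    """Proxy for the daily VPD maximum when sub-daily records are absent.

    Uses vpd(Tmax, RHmin); callers should flag series built this way.
    """
    return vpd(tmax, rh_min)


def et0_from_daily_frame(daily: pd.DataFrame, site: Site = Site()) -> pd.Series:
    """Attach FAO-56 ET0 to a daily frame indexed by date.

    Requires columns tmin, tmax, rh_mean, rs, u2.
    """
    doy = daily.index.dayofyear.to_numpy()
    et0 = daily_et0(
        daily["tmin"].to_numpy(), daily["tmax"].to_numpy(),
        daily["rh_mean"].to_numpy(), daily["rs"].to_numpy(),
        daily["u2"].to_numpy(), doy, site,
    )
    return pd.Series(et0, index=daily.index, name="et0_mm_d")


def read_weather_csv(path, timestamp_col: str = "timestamp",
                     columns: dict | None = None) -> pd.DataFrame:
    """Read a weather CSV with ISO-8601 timestamps.

    ``columns`` maps file column names to the canonical names
    (tair, rh, rs, u2, p); canonical names are used as-is when absent.
    """
    df = pd.read_csv(path)
    if timestamp_col not in df.columns:
        raise KeyError(f"missing timestamp column {timestamp_col!r}")
    try:
        ts = pd.to_datetime(df[timestamp_col], format="ISO8601")
    except (ValueError, TypeError) as exc:
        raise ValueError(f"malformed date column {timestamp_col!r}: {exc}") from exc
    df = df.drop(columns=[timestamp_col]).set_index(pd.DatetimeIndex(ts, name="timestamp"))
    if columns:
        df = df.rename(columns=columns)
    return df
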