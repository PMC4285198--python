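"""Synthetic annual dataset for a tropical sub-humid rubber stand.

Generates one year of daily drivers and pseudo-observations with the
seasonal structure the analysis assumes:

* evaporative demand: ET0 as a sinusoid peaking in mid-March (annual mean
  ~3.4 mm d-1, so the annual total sits near 1250 mm) plus Gaussian noise,
  clipped to [0.5, 10] mm d-1 — the observed range roughly 1-9 mm d-1;
* rainfall: wet season May-October with a mid-season dry spell
  (August-September) that drives topsoil REW below the critical value in the
  middle of the rains, and sparse dry-season showers November-April;
* phenology: piecewise-linear LAI with defoliation in January-February
  (LAI_max 3.9 down to LAI_min) and refoliation complete by end of April;
* soil: a single topsoil bucket (0-0.6 m, Wf 0.21 / Wm 0.07 m3 m-3) run
  daily with effective rainfall in and model-simulated uptake out; it only
  exists to produce realistic REW trajectories, including occasional
  REW > 1 waterlogging episodes;
* observations: pseudo-measured transpiration = model truth times
  multiplicative lognormal noise (mean exactly 1), because sap-flow errors
  scale with the flux; optionally inverted through the stand-scaling and
  TTD calibration into hourly Ka signals for testing the sap-flow chain.

Everything is reproducible bit-for-bit from (config, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import ModelParams, r_et0c, r_lai, r_rewc
from .sapflow import StandParams
from .soilwater import SoilLayer, SoilProfile, rew_series
from .constants import TTD_CALIBRATION_KG_M2_H

__all__ = [
    "SyntheticConfig",
    "generate_weather",
    "generate_phenology",
    "generate_soil_and_truth",
    "generate_observations",
    "ka_from_daily_transpiration",
    "generate_dataset",
]


@dataclass(frozen=True)
class SyntheticConfig:
    year: int = 2007
    n_days: int = 365
    # evaporative demand
    et0_mean: float = 3.42            # mm d-1 -> ~1248 mm yr-1
    et0_amplitude: float = 2.2        # mm d-1
    et0_peak_doy: int = 74            # mid-March
    et0_noise_sd: float = 0.6         # mm d-1
    et0_floor: float = 0.5
    et0_ceiling: float = 10.0
    # VPD co-generated with demand
    vpd_per_et0: float = 0.33         # kPa per mm d-1
    vpd_noise_sd: float = 0.12        # kPa
    vpd_floor: float = 0.15           # kPa
    # rainfall
    rain_p_wet: float = 0.50
    rain_p_dry: float = 0.08
    rain_shape_wet: float = 0.9
    rain_scale_wet: float = 12.0      # mean wet-day depth ~10.8 mm
    rain_shape_dry: float = 0.7
    rain_scale_dry: float = 5.0
    dry_spell_start_doy: int = 182    # mid-season drought from ~July 1
    dry_spell_end_doy: int = 225
    dry_spell_p_factor: float = 0.05
    # phenology (piecewise-linear LAI nodes, day-of-year)
    defoliation_start_doy: int = 1
    lai_min_doy: int = 50             # late February
    refoliation_end_doy: int = 120    # end of April
    lai_min: float = 0.4
    # topsoil bucket
    bucket_depth_m: float = 0.6
    wf: float = 0.21
    wm: float = 0.07
    w_init: float = 0.133             # REW ~0.45 on Jan 1 (mid dry season)
    infiltration_frac: float = 0.75
    infiltration_cap_mm: float = 25.0
    waterlog_margin: float = 0.01     # m3 m-3 above Wf
    # true model parameters and observation noise
    params: ModelParams = field(default_factory=ModelParams)
    obs_cv: float = 0.1

    @property
    def lai_max(self) -> float:
        return self.params.lai_max

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(f"{self.year}-01-01", periods=self.n_days,
                             freq="D", name="date")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["params"] = self.params.to_dict()
        return d


def _rngs(seed: int, n: int = 4):
    return [np.random.default_rng(s) for s in
            np.random.SeedSequence(seed).spawn(n)]


def generate_weather(config: SyntheticConfig = SyntheticConfig(),
                     seed: int = 0) -> pd.DataFrame:
    """Daily ET0 (mm d-1), rainfall (mm) and VPDmax (kPa) for one year."""
    rng_et0, rng_rain_occ, rng_rain_depth, rng_vpd = _rngs(seed)
    dates = config.dates()
    doy = dates.dayofyear.to_numpy().astype(float)

    phase = 2.0 * np.pi * (doy - config.et0_peak_doy) / 365.0
    et0 = config.et0_mean + config.et0_amplitude * np.cos(phase)
    et0 = et0 + rng_et0.normal(0.0, config.et0_noise_sd, size=doy.size)
    et0 = np.clip(et0, config.et0_floor, config.et0_ceiling)

    wet = (dates.month >= 5) & (dates.month <= 10)
    p_occ = np.where(wet, config.rain_p_wet, config.rain_p_dry)
    in_spell = (doy >= config.dry_spell_start_doy) & (doy <= config.dry_spell_end_doy)
    p_occ = np.where(in_spell, p_occ * config.dry_spell_p_factor, p_occ)
    rains = rng_rain_occ.random(doy.size) < p_occ
    shape = np.where(wet, config.rain_shape_wet, config.rain_shape_dry)
    scale = np.where(wet, config.rain_scale_wet, config.rain_scale_dry)
    depth = rng_rain_depth.gamma(shape, scale)
    p = np.where(rains, depth, 0.0)

    vpd = config.vpd_per_et0 * et0 + rng_vpd.normal(0.0, config.vpd_noise_sd,
                                                    size=doy.size)
    vpd = np.maximum(vpd, config.vpd_floor)

    return pd.DataFrame({"et0": et0, "p": p, "vpd_max": vpd}, index=dates)


def generate_phenology(config: SyntheticConfig = SyntheticConfig()) -> pd.Series:
    """Piecewise-linear daily LAI trajectory (deterministic)."""
    nodes_doy = (config.defoliation_start_doy, config.lai_min_doy,
                 config.refoliation_end_doy)
    if not nodes_doy[0] <= nodes_doy[1] <= nodes_doy[2]:
        raise ValueError(f"phenology nodes must be ordered, got {nodes_doy}")
    dates = config.dates()
    doy = dates.dayofyear.to_numpy().astype(float)
    xp = [1.0, float(nodes_doy[0]), float(nodes_doy[1]),
          float(nodes_doy[2]), float(config.n_days)]
    fp = [config.lai_max, config.lai_max, config.lai_min,
          config.lai_max, config.lai_max]
    # drop duplicated leading node when defoliation starts on Jan 1
    if xp[0] == xp[1]:
        xp, fp = xp[1:], fp[1:]
    lai = np.interp(doy, xp, fp)
    return pd.Series(lai, index=dates, name="lai")


def generate_soil_and_truth(weather: pd.DataFrame, lai: pd.Series,
                            config: SyntheticConfig = SyntheticConfig()) -> pd.DataFrame:
    """Daily bucket water balance coupled to the true model.

    Each day: REW from the bucket content, reduction factors from the true
    parameters, uptake = simulated transpiration, then the balance
    W(t+1) = clip(W(t) + (P_eff - T)/depth, Wm, Wf + waterlog_margin).

    Returns a frame with w, rew and the true (noise-free) transpiration
    t_true (mm d-1).
    """
    params = config.params
    depth_mm = config.bucket_depth_m * 1.0e3
    et0 = weather["et0"].to_numpy()
    p_eff = np.minimum(weather["p"].to_numpy() * config.infiltration_frac,
                       config.infiltration_cap_mm)
    rl = r_lai(lai.to_numpy(), params.lai_max)
    re = r_et0c(et0, params)
    n = et0.size
    w = np.empty(n)
    rew = np.empty(n)
    t_true = np.empty(n)
    span = config.wf - config.wm
    w_cur = config.w_init
    for i in range(n):
        w[i] = w_cur
        rew[i] = (w_cur - config.wm) / span
        rr = r_rewc(rew[i], params.rewc, rl[i])
        t_true[i] = min(rr, re[i]) * params.rm * et0[i]
        w_cur = np.clip(w_cur + (p_eff[i] - t_true[i]) / depth_mm,
                        config.wm, config.wf + config.waterlog_margin)
    return pd.DataFrame({"w": w, "rew": rew, "t_true": t_true},
                        index=weather.index)


def generate_observations(t_true: pd.Series, config: SyntheticConfig = SyntheticConfig(),
                          seed: int = 0) -> pd.Series:
    """Pseudo-measured transpiration with multiplicative lognormal noise.

    The lognormal is parameterised so its mean is exactly 1 at any cv
    (sigma^2 = ln(1+cv^2), mu = -sigma^2/2); cv = 0 returns the truth.
    """
    if config.obs_cv < 0:
        raise ValueError("observation cv must be non-negative")
    if config.obs_cv == 0:
        return t_true.rename("t_obs").copy()
    rng = np.random.default_rng(np.random.SeedSequence(seed).spawn(5)[4])
    sigma = np.sqrt(np.log1p(config.obs_cv**2))
    noise = rng.lognormal(-sigma**2 / 2.0, sigma, size=t_true.size)
    return pd.Series(t_true.to_numpy() * noise, index=t_true.index,
                     name="t_obs")


def ka_from_daily_transpiration(t_mm_d: pd.Series,
                                stand: StandParams = StandParams(),
                                daylight=(6, 18)) -> pd.Series:
    """Invert daily stand transpiration into an hourly Ka signal.

    Distributes each day's sapwood flux Jout_day over a half-sine diurnal
    course inside the daylight window and divides by the TTD calibration, so
    the forward chain (hourly flux -> daily total -> stand scaling) recovers
    the daily series exactly. Nighttime Ka is 0 (zero-flow assumption).
    """
    jout = t_mm_d.to_numpy() / (
        stand.radial_coeff * stand.sapwood_area_m2 / stand.spacing_area_m2)
    hours = np.arange(24)
    in_day = (hours >= daylight[0]) & (hours < daylight[1])
    shape = np.where(in_day,
                     np.sin(np.pi * (hours - daylight[0] + 0.5)
                            / (daylight[1] - daylight[0])),
                     0.0)
    shape = shape / shape.sum()
    idx = []
    vals = []
    for day, j in zip(t_mm_d.index, jout):
        idx.append(pd.date_range(day, periods=24, freq="h"))
        vals.append(j * shape / TTD_CALIBRATION_KG_M2_H)
    return pd.Series(np.concatenate(vals), index=idx[0].append(idx[1:]),
                     name="ka")


def soil_profile_from_config(config: SyntheticConfig) -> SoilProfile:
    """Three-layer topsoil profile matching the bucket constants."""
    bounds = [(0.0, 0.2, 0.63), (0.2, 0.4, 0.32), (0.4, 0.6, 0.05)]
    return SoilProfile(tuple(
        SoilLayer(a, b, config.wf, config.wm, f) for a, b, f in bounds))


def generate_dataset(config: SyntheticConfig = SyntheticConfig(),
                     seed: int = 0) -> dict:
    """Full annual dataset: drivers, soil states, truth and observations.

    Returns a dict with ``drivers`` (et0, lai, rew, p, vpd_max, daily),
    ``soil`` (per-layer water content and REW), ``t_true``, ``t_obs`` and
    the ``config`` used.
    """
    weather = generate_weather(config, seed)
    lai = generate_phenology(config)
    soil = generate_soil_and_truth(weather, lai, config)
    t_obs = generate_observations(soil["t_true"], config, seed)
    drivers = pd.DataFrame({
        "et0": weather["et0"],
        "lai": lai,
        "rew": soil["rew"],
        "p": weather["p"],
        "vpd_max": weather["vpd_max"],
    })
    profile = soil_profile_from_config(config)
    water = pd.DataFrame({f"w_{i}": soil["w"] for i in range(len(profile.layers))},
                         index=soil.index)
    soil_layers = rew_series(water, profile)
    soil_layers.insert(0, "w", soil["w"])
    return {
        "drivers": drivers,
        "soil": soil_layers,
        "t_true": soil["t_true"],
        "t_obs": t_obs,
        "config": config,
    }
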