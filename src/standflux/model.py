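"""Reduction-factor transpiration model.

Daily potential transpiration is proportional to the FAO-56 reference
evapotranspiration, T_max = rm * ET0, and is reduced by three multiplicative
or limiting constraints:

* canopy phenology:      r_LAI  = LAI / LAI_max
* soil water shortage:   r_REWc = r_LAI                  if REW > REWc
                                  (r_LAI / REWc) * REW   if REW <= REWc
* evaporative demand:    r_ET0c = 1                      if ET0 <= ET0c
                                  a * ln(ET0) + b        if ET0 >  ET0c
                                  (clamped into [0, 1])

The original framework's simulation is T_mod = r_REWc * T_max; the extended
framework takes the *minimum* of the soil and atmospheric constraints,
T_mod_ET0c = min(r_REWc, r_ET0c) * T_max. The high-demand factor expresses
isohydric stomatal regulation: transpiration saturates, then declines, above
a critical demand ET0c regardless of soil water.

As printed, the log law evaluates to about 0.762 at ET0c = 2.3 mm d-1, so the
default "piecewise_as_printed" mode has a downward jump there; the
alternative "continuous_min" mode uses min(1, a*ln(ET0)+b), which leaves 1
near ET0 = exp((1-b)/a) ~ 1.53 mm d-1 and is continuous.

`ReductionFactorModel` wraps calibration + simulation as a scikit-learn
estimator: `fit(X, y)` estimates (rm, a, b, ET0c, REWc) from daily driver /
measured-transpiration pairs, `predict(X)` returns the simulated daily
transpiration.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "ModelParams",
    "DEFAULT_PARAMS",
    "t_max",
    "r_lai",
    "r_rewc",
    "r_et0c",
    "simulate",
    "ReductionFactorModel",
]

DRIVER_COLUMNS = ("et0", "lai", "rew")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the reduction-factor model.

    Defaults are the calibrated values for a mature rubber stand under a
    tropical sub-humid climate: rm = 1.0, LAI_max = 3.9, REWc = 0.4,
    ET0c = 2.3 mm d-1 and the log-law coefficients a = -0.585, b = 1.2492.
    """

    rm: float = 1.0
    lai_max: float = 3.9
    rewc: float = 0.4
    et0c: float = 2.3
    a: float = -0.585
    b: float = 1.2492
    continuity_mode: str = "piecewise_as_printed"

    def __post_init__(self) -> None:
        if self.rm <= 0 or self.lai_max <= 0 or self.et0c <= 0:
            raise ValueError("rm, LAI_max and ET0c must be positive")
        if not 0.0 < self.rewc < 1.0:
            raise ValueError(f"REWc must be in (0, 1), got {self.rewc}")
        if self.continuity_mode not in ("piecewise_as_printed", "continuous_min"):
            raise ValueError(f"unknown continuity mode {self.continuity_mode!r}")

    def to_dict(self) -> dict:
        return asdict(self)

    def replace(self, **kwargs) -> "ModelParams":
        return replace(self, **kwargs)


DEFAULT_PARAMS = ModelParams()


def t_max(et0, rm: float = DEFAULT_PARAMS.rm):
    """Potential (climate-driven) transpiration, mm d-1: rm * ET0."""
    et0 = np.asarray(et0, dtype=float)
    if np.any(et0[~np.isnan(et0)] < 0):
        raise ValueError("ET0 must be non-negative")
    out = rm * et0
    return out if out.ndim else float(out)


def r_lai(lai, lai_max: float = DEFAULT_PARAMS.lai_max):
    """Phenological reduction factor LAI / LAI_max, clipped into [0, 1]."""
    lai = np.asarray(lai, dtype=float)
    if np.any(lai[~np.isnan(lai)] < 0):
        raise ValueError("LAI must be non-negative")
    ratio = lai / lai_max
    n_over = int(np.sum(ratio[~np.isnan(ratio)] > 1))
    if n_over:
        import warnings
        warnings.warn(f"{n_over} LAI value(s) above LAI_max clipped", stacklevel=2)
    out = np.clip(ratio, 0.0, 1.0)
    return out if out.ndim else float(out)


def r_rewc(rew, rewc: float = DEFAULT_PARAMS.rewc, rlai=1.0):
    """Soil-water reduction factor.

    Equals r_LAI above the critical REW, declines linearly to 0 below it:
    (r_LAI / REWc) * REW for REW <= REWc. REW values above 1 (waterlogging)
    simply saturate at r_LAI; the factor is continuous at REW = REWc.
    """
    rew = np.asarray(rew, dtype=float)
    if np.any(rew[~np.isnan(rew)] < 0):
        raise ValueError("REW must be non-negative")
    rlai = np.asarray(rlai, dtype=float)
    out = np.where(rew > rewc, rlai, (rlai / rewc) * rew)
    return out if out.ndim else float(out)


def r_et0c(et0, params: ModelParams = DEFAULT_PARAMS):
    """High-evaporative-demand reduction factor.

    1 for ET0 <= ET0c; a*ln(ET0) + b above, clamped into [0, 1] (the raw law
    turns negative near ET0 = exp(-b/a) ~ 8.5 mm d-1 at the default
    coefficients). In "continuous_min" mode the factor is min(1, a*ln(ET0)+b)
    over the whole range.
    """
    et0 = np.asarray(et0, dtype=float)
    if np.any(et0[~np.isnan(et0)] < 0):
        raise ValueError("ET0 must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        law = params.a * np.log(et0) + params.b
    law = np.clip(law, 0.0, 1.0)
    if params.continuity_mode == "continuous_min":
        out = law
    else:
        out = np.where(et0 <= params.et0c, 1.0, law)
    return out if out.ndim else float(out)


def _check_drivers(drivers: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in DRIVER_COLUMNS if c not in drivers.columns]
    if missing:
        raise ValueError(f"driver frame missing columns: {missing}")
    if drivers[list(DRIVER_COLUMNS)].isna().any().any():
        raise ValueError(
            "driver series contain gaps; fill or mask them before simulating")
    return drivers


def simulate(drivers: pd.DataFrame, params: ModelParams = DEFAULT_PARAMS) -> pd.DataFrame:
    """Run the daily model over aligned driver series.

    ``drivers`` must hold gap-free columns ``et0`` (mm d-1), ``lai`` and
    ``rew`` on a daily index. Returns the drivers plus t_max, the three
    reduction factors, ``t_mod`` (soil constraint only) and ``t_mod_et0c``
    (soil and atmospheric constraints combined by their minimum).
    """
    _check_drivers(drivers)
    et0 = drivers["et0"].to_numpy()
    out = drivers.copy()
    out["t_max"] = t_max(et0, params.rm)
    rl = r_lai(drivers["lai"].to_numpy(), params.lai_max)
    rr = r_rewc(drivers["rew"].to_numpy(), params.rewc, rl)
    re = r_et0c(et0, params)
    out["r_lai"] = rl
    out["r_rewc"] = rr
    out["r_et0c"] = re
    out["t_mod"] = rr * out["t_max"]
    out["t_mod_et0c"] = np.minimum(rr, re) * out["t_max"]
    return out


class ReductionFactorModel(BaseEstimator, RegressorMixin):
    """Scikit-learn estimator wrapping calibration and simulation.

    Parameters double as initial/fixed values; ``fit`` re-estimates
    (et0c_, rm_, a_, b_, rewc_) from data when ``y`` (measured daily
    transpiration, mm d-1) is given, and simply adopts the constructor
    values when ``y`` is None (pure simulation with fixed parameters).

    ``X`` is a DataFrame with columns ``et0``, ``lai``, ``rew`` (or an
    (n, 3) array in that column order).
    """

    def __init__(self, rm=1.0, lai_max=3.9, rewc=0.4, et0c=2.3,
                 a=-0.585, b=1.2492, continuity_mode="piecewise_as_printed",
                 rew_nonlimiting=0.5, full_canopy_frac=0.99,
                 et0c_grid_step=0.1, rewc_grid_step=0.05):
        self.rm = rm
        self.lai_max = lai_max
        self.rewc = rewc
        self.et0c = et0c
        self.a = a
        self.b = b
        self.continuity_mode = continuity_mode
        self.rew_nonlimiting = rew_nonlimiting
        self.full_canopy_frac = full_canopy_frac
        self.et0c_grid_step = et0c_grid_step
        self.rewc_grid_step = rewc_grid_step

    def _as_frame(self, X) -> pd.DataFrame:
        if isinstance(X, pd.DataFrame):
            return _check_drivers(X)
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 3:
            raise ValueError("expected (n, 3) drivers: et0, lai, rew")
        return pd.DataFrame(X, columns=list(DRIVER_COLUMNS))

    def fit(self, X, y=None):
        from . import calibration

        drivers = self._as_frame(X)
        if y is None:
            self.rm_, self.a_, self.b_ = self.rm, self.a, self.b
            self.et0c_, self.rewc_ = self.et0c, self.rewc
            self.calibration_ = {"source": "fixed"}
        else:
            t_obs = np.asarray(y, dtype=float)
            result = calibration.calibrate(
                drivers["et0"].to_numpy(), drivers["lai"].to_numpy(),
                drivers["rew"].to_numpy(), t_obs,
                lai_max=self.lai_max,
                rew_nonlimiting=self.rew_nonlimiting,
                full_canopy_frac=self.full_canopy_frac,
                et0c_grid_step=self.et0c_grid_step,
                rewc_grid_step=self.rewc_grid_step,
            )
            self.rm_ = result["rm"]
            self.a_ = result["a"]
            self.b_ = result["b"]
            self.et0c_ = result["et0c"]
            self.rewc_ = result["rewc"]
            self.calibration_ = result
        self.params_ = ModelParams(
            rm=self.rm_, lai_max=self.lai_max, rewc=self.rewc_,
            et0c=self.et0c_, a=self.a_, b=self.b_,
            continuity_mode=self.continuity_mode)
        self.n_features_in_ = 3
        return self

    def simulate(self, X) -> pd.DataFrame:
        check_is_fitted(self, "params_")
        return simulate(self._as_frame(X), self.params_)

    def predict(self, X):
        """Simulated daily transpiration T_mod_ET0c, mm d-1."""
        return self.simulate(X)["t_mod_et0c"].to_numpy()
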