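"""Canopy conductance from inverted Penman-Monteith and its VPD response.

For a canopy well coupled to the atmosphere (decoupling coefficient near 0),
transpiration is conductance-limited and the Penman-Monteith equation
inverts to

    Gc = gamma * lambda * T / (Cp * rho * VPD)

with T the transpiration mass flux (kg m-2 s-1) and VPD in Pa; Gc is
returned in mm s-1. The daily midday conductance pairs each day's maximum
VPD with its maximum transpiration rate.

The stomatal response to atmospheric drought is summarised by the log-linear
form Gc = G_ref - m * ln(VPD_kPa) (the reference conductance G_ref is the
value at VPD = 1 kPa exactly); a hyperbolic Lohammar form
Gc = G_ref / (1 + VPD/VPD0) is available as an option.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import constants

__all__ = [
    "PhysicalConstants",
    "canopy_conductance",
    "transpiration_rate",
    "midday_conductance",
    "fit_gc_vpd",
]


@dataclass(frozen=True)
class PhysicalConstants:
    gamma_pa_k: float = constants.GAMMA_PA_K
    lambda_j_kg: float = constants.LAMBDA_J_KG
    cp_j_kg_k: float = constants.CP_J_KG_K
    rho_kg_m3: float = constants.RHO_KG_M3

    def __post_init__(self) -> None:
        for name, v in self.__dict__.items():
            if v <= 0:
                raise ValueError(f"{name} must be strictly positive")


DEFAULT_CONSTANTS = PhysicalConstants()


def canopy_conductance(t_rate, vpd_pa, consts: PhysicalConstants = DEFAULT_CONSTANTS,
                       vpd_floor_pa: float = 100.0):
    """Canopy conductance Gc (mm s-1) from transpiration rate and VPD.

    ``t_rate`` is a mass flux in kg m-2 s-1, ``vpd_pa`` in Pa. Records with
    VPD below ``vpd_floor_pa`` are undefined (NaN): the well-coupled
    inversion degenerates as VPD -> 0.
    """
    t = np.asarray(t_rate, dtype=float)
    v = np.asarray(vpd_pa, dtype=float)
    if np.any(t[~np.isnan(t)] < 0):
        raise ValueError("transpiration rate must be non-negative")
    with np.errstate(divide="ignore", invalid="ignore"):
        gc_m_s = consts.gamma_pa_k * consts.lambda_j_kg * t / (
            consts.cp_j_kg_k * consts.rho_kg_m3 * v)
    gc = np.where(v >= vpd_floor_pa, gc_m_s * 1.0e3, np.nan)
    return gc if np.ndim(gc) else float(gc)


def transpiration_rate(t_mm_d, daylight_hours: float = 12.0,
                       peak_factor: float = np.pi / 2.0):
    """Daily maximum transpiration mass flux (kg m-2 s-1) from a daily total.

    The daily depth (mm = kg m-2) is assumed to be transpired over an
    effective daylight duration with a half-sine diurnal course, whose peak
    is pi/2 times the daylight mean. Used when sub-daily sap-flow rates are
    not carried through; series built this way should be flagged.
    """
    t = np.asarray(t_mm_d, dtype=float)
    rate = peak_factor * t / (daylight_hours * 3600.0)
    return rate if rate.ndim else float(rate)


def midday_conductance(t_mm_d, vpd_max_kpa,
                       consts: PhysicalConstants = DEFAULT_CONSTANTS,
                       daylight_hours: float = 12.0,
                       vpd_floor_pa: float = 100.0) -> pd.DataFrame:
    """Daily midday canopy conductance from daily-extrema pairing.

    Pairs each day's VPD maximum with its maximum transpiration rate (the
    two need not be simultaneous). Returns a frame with the rate, VPD and
    Gc_md plus the count of records skipped below the VPD floor.
    """
    rate = transpiration_rate(t_mm_d, daylight_hours)
    vpd_pa = np.asarray(vpd_max_kpa, dtype=float) * 1.0e3
    gc = canopy_conductance(rate, vpd_pa, consts, vpd_floor_pa)
    df = pd.DataFrame({"t_rate": rate, "vpd_max_kpa": np.asarray(vpd_max_kpa, float),
                       "gc_md": gc})
    df.attrs["n_below_floor"] = int(np.sum(vpd_pa < vpd_floor_pa))
    return df


def fit_gc_vpd(vpd_kpa, gc, form: str = "loglinear", min_records: int = 5,
               min_span_kpa: float = 0.5):
    """Fit the conductance-VPD response.

    form="loglinear": Gc = G_ref - m * ln(VPD_kPa); G_ref is exactly the
    fitted conductance at 1 kPa, m the sensitivity (mm s-1 per ln kPa).
    form="lohammar": Gc = G_ref2 / (1 + VPD/VPD0) (hyperbolic), fitted by
    nonlinear least squares.

    Requires >= ``min_records`` records spanning >= ``min_span_kpa`` of VPD.
    """
    v = np.asarray(vpd_kpa, dtype=float)
    g = np.asarray(gc, dtype=float)
    mask = ~(np.isnan(v) | np.isnan(g)) & (v > 0)
    v, g = v[mask], g[mask]
    if v.size < min_records:
        raise ValueError(f"need >= {min_records} records, got {v.size}")
    if np.ptp(v) < min_span_kpa:
        raise ValueError(
            f"VPD span {np.ptp(v):.3f} kPa below required {min_span_kpa}; "
            "no slope identifiable")
    if form == "loglinear":
        lx = np.log(v)
        A = np.column_stack([-lx, np.ones_like(lx)])
        coef, *_ = np.linalg.lstsq(A, g, rcond=None)
        m, g_ref = float(coef[0]), float(coef[1])
        pred = g_ref - m * lx
    elif form == "lohammar":
        def f(x, g_ref2, vpd0):
            return g_ref2 / (1.0 + x / vpd0)
        (g_ref2, vpd0), _ = optimize.curve_fit(
            f, v, g, p0=[max(g.max(), 1e-6), 1.0], maxfev=10000)
        pred = f(v, g_ref2, vpd0)
        m, g_ref = float(g_ref2 / vpd0 / 4.0), float(f(1.0, g_ref2, vpd0))
        # g_ref reported at 1 kPa for comparability; slope proxy at VPD0
    else:
        raise ValueError(f"unknown form {form!r}")
    ss_res = float(np.sum((g - pred) ** 2))
    ss_tot = float(np.sum((g - g.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    out = {"g_ref": g_ref, "sensitivity": m, "r2": r2, "n": int(v.size),
           "form": form}
    if form == "lohammar":
        out["g_ref_asymptote"] = float(g_ref2)
        out["vpd0"] = float(vpd0)
    return out
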