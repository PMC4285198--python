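"""Parameter estimation from paired daily (ET0, LAI, REW, T) data.

The calibration mirrors how the model parameters are identified in practice:

* ``fit_rm`` — through-origin regression of measured maximal transpiration on
  ET0, restricted to full-canopy days with non-limiting soil water
  (REW >= 0.5) and low demand (ET0 below the critical value).
* ``fit_ratio_loglaw`` — least squares of the relative transpiration
  T/ET0 against ln(ET0) (ratios above 1 discarded first), giving the
  high-demand law coefficients a (slope) and b (intercept).
* ``estimate_et0c`` — breakpoint of a two-segment model (through-origin line
  joined to the log law), grid-searched to minimise total squared error.
* ``estimate_rewc`` — broken-stick fit of T/ET0 against REW (plateau above
  the breakpoint, line through the origin below), grid-searched.

The threshold parameters were originally read off scatter plots; the grid
searches formalise that reading into a reproducible estimator.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "fit_rm",
    "fit_ratio_loglaw",
    "estimate_et0c",
    "estimate_rewc",
    "calibrate",
]


def _clean_pairs(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    return x[mask], y[mask]


def fit_rm(et0, t_obs, min_pairs: int = 5):
    """Through-origin slope of T on ET0 with its standard error.

    Caller applies the non-limiting filters; this is the plain estimator
    rm = sum(x*y) / sum(x^2).
    """
    x, y = _clean_pairs(et0, t_obs)
    if x.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs after filtering, got {x.size}")
    sxx = float(np.sum(x * x))
    if sxx == 0:
        raise ValueError("ET0 values are all zero")
    slope = float(np.sum(x * y)) / sxx
    resid = y - slope * x
    dof = max(x.size - 1, 1)
    se = float(np.sqrt(np.sum(resid**2) / dof / sxx))
    return {"rm": slope, "se": se, "n": int(x.size)}


def fit_ratio_loglaw(et0, ratio, min_pairs: int = 5, min_span: float = 2.0,
                     discard_above: float = 1.0):
    """Least-squares fit of T/ET0 = a*ln(ET0) + b.

    Ratios above ``discard_above`` (default 1, attributable to reference-crop
    mismatch and sap-flow overestimation at low flows) are discarded before
    fitting. Requires the retained ET0 values to span at least ``min_span``
    mm d-1.
    """
    x, y = _clean_pairs(et0, ratio)
    keep = y <= discard_above
    x, y = x[keep], y[keep]
    if x.size < min_pairs:
        raise ValueError(f"need >= {min_pairs} pairs after discarding, got {x.size}")
    if np.ptp(x) < min_span:
        raise ValueError(
            f"ET0 span {np.ptp(x):.2f} mm/d below required {min_span}")
    lx = np.log(x)
    A = np.column_stack([lx, np.ones_like(lx)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    a, b = float(coef[0]), float(coef[1])
    pred = a * lx + b
    ss_res = float(np.sum((y - pred) ** 2))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
    return {"a": a, "b": b, "r2": r2, "n": int(x.size),
            "n_discarded": int(np.sum(~keep))}


def estimate_et0c(et0, t_obs, grid=None, grid_step: float = 0.1,
                  min_below: int = 3, min_above: int = 3):
    """Breakpoint ET0c of a two-segment (linear / log-law) demand response.

    For each candidate c the data are split at ET0 = c: a through-origin
    line T = s*ET0 is fitted below and the log law T = (a*ln(ET0)+b)*ET0
    above; the candidate minimising the total squared error on T wins.
    A flat SSE profile (e.g. purely linear data, which both segments fit
    exactly everywhere) is degenerate: the upper grid edge is returned with
    ``flagged=True``.
    """
    x, y = _clean_pairs(et0, t_obs)
    if grid is None:
        lo = np.quantile(x, 0.05) if x.size else 1.0
        grid = np.arange(max(round(lo, 1), 1.0), 5.0 + grid_step / 2, grid_step)
    grid = np.asarray(grid, dtype=float)
    sses, cands = [], []
    for c in grid:
        below = x <= c
        above = ~below
        if below.sum() < min_below or above.sum() < min_above:
            continue
        s = np.sum(x[below] * y[below]) / np.sum(x[below] ** 2)
        lx = np.log(x[above])
        A = np.column_stack([lx, np.ones_like(lx)])
        coef, *_ = np.linalg.lstsq(A, y[above] / x[above], rcond=None)
        pred_above = (coef[0] * lx + coef[1]) * x[above]
        sse = float(np.sum((y[below] - s * x[below]) ** 2)
                    + np.sum((y[above] - pred_above) ** 2))
        sses.append(sse)
        cands.append(float(c))
    if not cands:
        raise ValueError("no candidate breakpoint with enough data on both sides")
    sses = np.asarray(sses)
    flat = (sses.max() - sses.min()) <= 1e-10 * (1.0 + sses.min())
    if flat:
        return {"et0c": cands[-1], "sse": float(sses[-1]), "flagged": True,
                "grid": cands}
    i = int(np.argmin(sses))
    return {"et0c": cands[i], "sse": float(sses[i]), "flagged": False,
            "grid": cands}


def estimate_rewc(rew, ratio, grid=None, grid_step: float = 0.05,
                  min_below: int = 3, nonlimiting: float = 0.5):
    """Broken-stick breakpoint REWc of the soil-water response.

    The relative transpiration T/ET0 is modelled as a plateau (its mean)
    above the breakpoint and a line through the origin reaching the plateau
    at the breakpoint below it. Grid search over [0.1, 0.8] by default.
    Unidentifiable without sub-threshold data: requires at least
    ``min_below`` points with REW below the non-limiting cutoff.
    """
    x, y = _clean_pairs(rew, ratio)
    if int(np.sum(x < nonlimiting)) < min_below:
        raise ValueError(
            "REWc unidentifiable: no (or too few) observations below the "
            f"non-limiting REW cutoff {nonlimiting}")
    if grid is None:
        grid = np.arange(0.1, 0.8 + grid_step / 2, grid_step)
    best = None
    for c in np.asarray(grid, dtype=float):
        above = x > c
        if above.sum() < 2 or (~above).sum() < 1:
            continue
        plateau = float(np.mean(y[above]))
        pred = np.where(above, plateau, plateau * x / c)
        sse = float(np.sum((y - pred) ** 2))
        if best is None or sse < best[1]:
            best = (float(c), sse, plateau)
    if best is None:
        raise ValueError("no valid breakpoint candidate")
    return {"rewc": best[0], "sse": best[1], "plateau": best[2]}


def calibrate(et0, lai, rew, t_obs, *, lai_max: float = 3.9,
              rew_nonlimiting: float = 0.5, full_canopy_frac: float = 0.99,
              et0c_grid_step: float = 0.1, rewc_grid_step: float = 0.05) -> dict:
    """Full calibration pipeline on aligned daily series.

    1. restrict to full-canopy days (LAI >= full_canopy_frac * LAI_max);
    2. estimate ET0c on non-limiting-soil days (REW >= rew_nonlimiting);
    3. fit rm on the sub-critical-demand subset of those days;
    4. fit the log law (a, b) on the super-critical subset (ratios > 1
       discarded);
    5. estimate REWc from T/ET0 vs REW on sub-critical-demand full-canopy
       days (so the demand constraint cannot bind).
    """
    et0 = np.asarray(et0, dtype=float)
    lai = np.asarray(lai, dtype=float)
    rew = np.asarray(rew, dtype=float)
    t_obs = np.asarray(t_obs, dtype=float)
    full = lai >= full_canopy_frac * lai_max
    wet = rew >= rew_nonlimiting

    sel = full & wet
    et0c_fit = estimate_et0c(et0[sel], t_obs[sel], grid_step=et0c_grid_step)
    et0c = et0c_fit["et0c"]

    low = sel & (et0 < et0c)
    rm_fit = fit_rm(et0[low], t_obs[low])

    high = sel & (et0 > et0c)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(et0 > 0, t_obs / et0, np.nan)
    loglaw_fit = fit_ratio_loglaw(et0[high], ratio[high])

    soil = full & (et0 < et0c)
    rewc_fit = estimate_rewc(rew[soil], ratio[soil], grid_step=rewc_grid_step,
                             nonlimiting=rew_nonlimiting)

    return {
        "rm": rm_fit["rm"], "rm_se": rm_fit["se"],
        "a": loglaw_fit["a"], "b": loglaw_fit["b"], "r2_loglaw": loglaw_fit["r2"],
        "et0c": et0c, "et0c_flagged": et0c_fit["flagged"],
        "rewc": rewc_fit["rewc"], "rewc_plateau": rewc_fit["plateau"],
        "n_full_canopy": int(full.sum()), "n_nonlimiting": int(sel.sum()),
        "n_rm": rm_fit["n"], "n_loglaw": loglaw_fit["n"],
    }
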