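"""Model evaluation: agreement metrics, gap filling, seasonal accounting.

RMSE and RRMSE follow the standard per-point definitions

    RMSE  = sqrt( sum (x_mea - x_mod)^2 / n )
    RRMSE = sqrt( sum ((x_mea - x_mod)/x_mea)^2 / n )

with near-zero measured values excluded from the relative error (they blow
the ratio up; the exclusion count is reported). R2 is the squared Pearson
correlation of the measured-simulated pairing.

Seasonal windows for a tropical sub-humid annual cycle: rainy season May 1 -
October 31, dry season November-April (calendar-clipped within the analysis
year: January-April plus November-December).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "metrics",
    "gap_fill",
    "SeasonWindows",
    "season_of",
    "seasonal_summary",
    "metrics_by_season",
    "relative_excess_pct",
]


def metrics(x_mea, x_mod, rrmse_floor: float = 0.05) -> dict:
    """R2, RMSE and RRMSE between measured and simulated series.

    Points missing in either series are dropped pairwise; measured values
    with |x_mea| < ``rrmse_floor`` are excluded from RRMSE only (count
    reported as ``n_excluded_rrmse``). R2 is NaN when either series has zero
    variance.
    """
    mea = np.asarray(x_mea, dtype=float)
    mod = np.asarray(x_mod, dtype=float)
    if mea.shape != mod.shape:
        raise ValueError("series must be aligned with identical shape")
    mask = ~(np.isnan(mea) | np.isnan(mod))
    mea, mod = mea[mask], mod[mask]
    n = mea.size
    if n == 0:
        raise ValueError("no overlapping observations")
    err = mea - mod
    rmse = float(np.sqrt(np.mean(err**2)))
    rel_ok = np.abs(mea) >= rrmse_floor
    if rel_ok.sum() > 0:
        rrmse = float(np.sqrt(np.mean((err[rel_ok] / mea[rel_ok]) ** 2)))
    else:
        rrmse = np.nan
    if np.std(mea) > 0 and np.std(mod) > 0:
        r2 = float(np.corrcoef(mea, mod)[0, 1] ** 2)
    else:
        r2 = np.nan
    return {"r2": r2, "rmse": rmse, "rrmse": rrmse, "n": int(n),
            "n_excluded_rrmse": int(n - rel_ok.sum())}


def gap_fill(t: pd.Series, et0: pd.Series, min_neighbours: int = 4,
             side_window: int = 7, max_gap: int = 14):
    """Fill gaps in a daily transpiration series from the local T/ET0 ratio.

    Each run of missing days no longer than ``max_gap`` is filled with
    ET0 * mean(T/ET0), the ratio averaged over at least ``min_neighbours``
    valid days surrounding the gap (up to ``side_window`` days on each
    side, split across both sides where possible). Gaps with too few
    surrounding days are left missing and flagged. Observed values are
    never altered.

    Returns (filled series, fill mask, unfilled-gap flag mask).
    """
    t = t.copy()
    if not t.index.equals(et0.index):
        raise ValueError("series must share the same index")
    isna = t.isna().to_numpy()
    filled = np.zeros(t.size, dtype=bool)
    unfilled = np.zeros(t.size, dtype=bool)
    ratio = (t / et0).to_numpy()
    i = 0
    while i < t.size:
        if not isna[i]:
            i += 1
            continue
        j = i
        while j < t.size and isna[j]:
            j += 1
        gap = slice(i, j)
        if (j - i) <= max_gap:
            left = [k for k in range(max(0, i - side_window), i) if not isna[k]]
            right = [k for k in range(j, min(t.size, j + side_window)) if not isna[k]]
            neigh = left[-min_neighbours:] + right[:min_neighbours]
            if len(neigh) >= min_neighbours:
                mean_ratio = float(np.nanmean(ratio[neigh]))
                t.iloc[gap] = mean_ratio * et0.iloc[gap]
                filled[gap] = True
            else:
                unfilled[gap] = True
        else:
            unfilled[gap] = True
        i = j
    return t, pd.Series(filled, index=t.index), pd.Series(unfilled, index=t.index)


@dataclass(frozen=True)
class SeasonWindows:
    """Calendar windows of the annual cycle (month, day) bounds."""

    rainy_start: tuple[int, int] = (5, 1)
    rainy_end: tuple[int, int] = (10, 31)

    def masks(self, index: pd.DatetimeIndex) -> dict[str, np.ndarray]:
        md = list(zip(index.month, index.day))
        rainy = np.array([self.rainy_start <= x <= self.rainy_end for x in md])
        return {
            "annual": np.ones(len(index), dtype=bool),
            "rainy": rainy,
            "dry": ~rainy,
        }


def season_of(index: pd.DatetimeIndex,
              windows: SeasonWindows = SeasonWindows()) -> pd.Series:
    """Label each day 'rainy' or 'dry'."""
    m = windows.masks(index)
    return pd.Series(np.where(m["rainy"], "rainy", "dry"), index=index)


def seasonal_summary(series: pd.Series,
                     windows: SeasonWindows = SeasonWindows()) -> pd.DataFrame:
    """Cumulative totals (mm) per window; totals with missing days are
    flagged partial."""
    masks = windows.masks(pd.DatetimeIndex(series.index))
    rows = []
    for name, mask in masks.items():
        sub = series[mask]
        rows.append({
            "window": name,
            "total": float(sub.sum(skipna=True)),
            "n_days": int(mask.sum()),
            "n_missing": int(sub.isna().sum()),
            "partial": bool(sub.isna().any()),
        })
    return pd.DataFrame(rows).set_index("window")


def metrics_by_season(frame: pd.DataFrame, mea_col: str, mod_cols,
                      windows: SeasonWindows = SeasonWindows(),
                      rrmse_floor: float = 0.05) -> pd.DataFrame:
    """Evaluation table: one row per (model, window) with R2/RMSE/RRMSE/n."""
    masks = windows.masks(pd.DatetimeIndex(frame.index))
    rows = []
    for col in mod_cols:
        for name, mask in masks.items():
            m = metrics(frame.loc[mask, mea_col], frame.loc[mask, col],
                        rrmse_floor=rrmse_floor)
            rows.append({"model": col, "window": name, **m})
    return pd.DataFrame(rows)


def relative_excess_pct(larger: float, smaller: float) -> float:
    """Percentage by which ``larger`` exceeds ``smaller``, relative to
    ``larger``: 100 * (larger - smaller) / larger."""
    if larger <= 0:
        raise ValueError("reference total must be positive")
    return 100.0 * (larger - smaller) / larger
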