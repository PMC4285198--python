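"""Factorial hierarchy of water constraints on transpiration.

Runs the model with every subset of the constraint set {LAI, REWc, ET0c}
switched on, cumulates transpiration per season window, and expresses each
run as a regulation ratio against the cumulated potential transpiration
(rm * ET0 at full canopy, no reductions). The reduction percentages rank the
constraints: canopy phenology vs soil water shortage vs atmospheric demand.

Factor semantics under partial subsets: the soil factor as defined couples
the phenology factor into its slope; when REWc is active without LAI, that
slope uses 1 instead of r_LAI — the only reading under which a
singleton-REWc run is well defined. Subsets combine soil-side factors with
the atmospheric factor by a minimum, so adding a factor can never increase
simulated transpiration.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pandas as pd

from .evaluation import SeasonWindows
from .model import DEFAULT_PARAMS, ModelParams, r_et0c, r_lai, r_rewc, t_max

__all__ = ["FACTORS", "all_subsets", "factor_series", "run_factorial",
           "reduction_percent", "plot_hierarchy"]

FACTORS = ("lai", "rewc", "et0c")


def all_subsets() -> list[tuple[str, ...]]:
    """The 8 subsets of {lai, rewc, et0c}, from empty to full."""
    out = []
    for k in range(len(FACTORS) + 1):
        out.extend(combinations(FACTORS, k))
    return out


def subset_label(subset) -> str:
    return "none" if not subset else "x".join(subset)


def factor_series(drivers: pd.DataFrame, subset,
                  params: ModelParams = DEFAULT_PARAMS) -> np.ndarray:
    """Daily combined reduction factor for one active-constraint subset."""
    subset = set(subset)
    unknown = subset - set(FACTORS)
    if unknown:
        raise ValueError(f"unknown factors: {sorted(unknown)}")
    n = len(drivers)
    rl = (r_lai(drivers["lai"].to_numpy(), params.lai_max)
          if "lai" in subset else np.ones(n))
    if "rewc" in subset:
        soil = r_rewc(drivers["rew"].to_numpy(), params.rewc, rl)
    else:
        soil = rl
    if "et0c" in subset:
        factor = np.minimum(soil, r_et0c(drivers["et0"].to_numpy(), params))
    else:
        factor = soil
    return factor


def reduction_percent(t_constrained: float, t_potential: float) -> float:
    """Percent reduction of a cumulated constrained run vs the potential:
    100 * (1 - T_constrained / T_potential)."""
    if t_potential <= 0:
        raise ValueError("potential transpiration must be positive")
    return 100.0 * (1.0 - t_constrained / t_potential)


def run_factorial(drivers: pd.DataFrame, params: ModelParams = DEFAULT_PARAMS,
                  windows: SeasonWindows = SeasonWindows()) -> pd.DataFrame:
    """Cumulative regulation ratios for all 8 factor subsets x 3 windows.

    ``drivers`` must be a gap-free daily frame with columns et0, lai, rew
    over the analysis year. Returns a long-format frame with columns
    subset, window, t_cum, t_potential, ratio, reduction_pct.
    """
    for col in ("et0", "lai", "rew"):
        if col not in drivers.columns:
            raise ValueError(f"driver frame missing column {col!r}")
    if drivers[["et0", "lai", "rew"]].isna().any().any():
        raise ValueError("driver series contain gaps; fill them first")
    tmax = t_max(drivers["et0"].to_numpy(), params.rm)
    masks = windows.masks(pd.DatetimeIndex(drivers.index))
    rows = []
    for subset in all_subsets():
        t_daily = factor_series(drivers, subset, params) * tmax
        for name, mask in masks.items():
            if not mask.any():
                continue  # window absent from the driver period
            pot = float(tmax[mask].sum())
            cum = float(t_daily[mask].sum())
            rows.append({
                "subset": subset_label(subset),
                "window": name,
                "t_cum": cum,
                "t_potential": pot,
                "ratio": cum / pot,
                "reduction_pct": reduction_percent(cum, pot),
            })
    return pd.DataFrame(rows)


def plot_hierarchy(result: pd.DataFrame, path=None):
    """Bar chart of reduction percentages per subset, one panel per window."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    windows = list(dict.fromkeys(result["window"]))
    fig, axes = plt.subplots(1, len(windows), figsize=(4 * len(windows), 4),
                             sharey=True)
    axes = np.atleast_1d(axes)
    for ax, win in zip(axes, windows):
        sub = result[result["window"] == win]
        ax.bar(sub["subset"], -sub["reduction_pct"], color="#4477aa")
        ax.set_title(win)
        ax.set_ylabel("regulation of transpiration (%)")
        ax.tick_params(axis="x", rotation=60)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
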