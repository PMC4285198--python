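"""Relative extractable soil water (REW).

Each layer's volumetric water content W is rescaled between its minimum
(wilting) content Wm and field capacity Wf:

    REW_i = (W - Wm) / (Wf - Wm)

and the topsoil REW driving the model is the fine-root-length-weighted sum of
layer values over the active zone (default 0-0.6 m, weights 0.63/0.32/0.05
for 0-0.2/0.2-0.4/0.4-0.6 m). Values above 1 indicate temporary waterlogging
and are kept (the model's soil reduction factor saturates anyway); values
below 0 are clipped with a warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "SoilLayer",
    "SoilProfile",
    "layer_rew",
    "weighted_rew",
    "cross_calibrate_sensor",
    "rew_series",
    "interpolate_to_daily",
]

_WEIGHT_TOL = 1e-9


@dataclass(frozen=True)
class SoilLayer:
    """Constants of one soil layer of the active root zone."""

    top_depth: float          # m
    bottom_depth: float       # m
    wf: float                 # field capacity, m3 m-3
    wm: float                 # minimum (wilting) water content, m3 m-3
    root_fraction: float      # fine-root-length weight, dimensionless

    def __post_init__(self) -> None:
        if self.wf <= self.wm or self.wm <= 0:
            raise ValueError(
                f"need Wf > Wm > 0, got Wf={self.wf}, Wm={self.wm}")
        if self.bottom_depth <= self.top_depth:
            raise ValueError("layer depths must increase")
        if self.root_fraction < 0:
            raise ValueError("root fraction must be non-negative")


def _default_layers() -> tuple[SoilLayer, ...]:
    # topsoil 0-0.6 m: Wf 0.21, Wm 0.07 m3 m-3; root-length weights
    # 0.63 / 0.32 / 0.05 over 0-0.2 / 0.2-0.4 / 0.4-0.6 m
    return (
        SoilLayer(0.0, 0.2, 0.21, 0.07, 0.63),
        SoilLayer(0.2, 0.4, 0.21, 0.07, 0.32),
        SoilLayer(0.4, 0.6, 0.21, 0.07, 0.05),
    )


@dataclass(frozen=True)
class SoilProfile:
    """Active-zone layer stack with validated depth ordering and weights."""

    layers: tuple[SoilLayer, ...] = field(default_factory=_default_layers)

    def __post_init__(self) -> None:
        layers = tuple(self.layers)
        object.__setattr__(self, "layers", layers)
        for above, below in zip(layers, layers[1:]):
            if below.top_depth < above.bottom_depth - 1e-12:
                raise ValueError("layers overlap")
        total = sum(l.root_fraction for l in layers)
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"root fractions must sum to 1, got {total}")

    @property
    def root_fractions(self) -> np.ndarray:
        return np.array([l.root_fraction for l in self.layers])


def layer_rew(w, layer: SoilLayer):
    """Relative extractable water of one layer from its water content.

    Negative values (W < Wm) are clipped to 0 with a warning; values above 1
    (W > Wf, waterlogging) are kept.
    """
    w = np.asarray(w, dtype=float)
    rew = (w - layer.wm) / (layer.wf - layer.wm)
    n_neg = int(np.sum(rew < 0))
    if n_neg:
        warnings.warn(
            f"{n_neg} water content value(s) below Wm clipped to REW=0",
            stacklevel=2)
        rew = np.maximum(rew, 0.0)
    return rew if rew.ndim else float(rew)


def weighted_rew(rew_by_layer, profile: SoilProfile = SoilProfile()):
    """Root-fraction-weighted REW over the active zone.

    ``rew_by_layer`` is an array of shape (..., n_layers) matching the
    profile's layer order.
    """
    rew = np.asarray(rew_by_layer, dtype=float)
    w = profile.root_fractions
    if rew.shape[-1] != w.size:
        raise ValueError(
            f"expected {w.size} layers, got {rew.shape[-1]}")
    if abs(w.sum() - 1.0) > 1e-6:
        raise ValueError("root fractions must sum to 1")
    out = rew @ w
    return out if np.ndim(out) else float(out)


def rew_series(water: pd.DataFrame, profile: SoilProfile = SoilProfile()) -> pd.DataFrame:
    """Per-layer and weighted REW from a date-indexed water-content frame.

    ``water`` columns are matched positionally to the profile layers.
    Returns columns ``rew_<i>`` per layer plus ``rew_weighted``.
    """
    if water.shape[1] != len(profile.layers):
        raise ValueError(
            f"expected {len(profile.layers)} water-content columns, "
            f"got {water.shape[1]}")
    out = pd.DataFrame(index=water.index)
    for i, layer in enumerate(profile.layers):
        out[f"rew_{i}"] = layer_rew(water.iloc[:, i].to_numpy(), layer)
    out["rew_weighted"] = weighted_rew(
        out[[f"rew_{i}" for i in range(len(profile.layers))]].to_numpy(),
        profile)
    return out


def interpolate_to_daily(series: pd.Series, freq: str = "D") -> pd.Series:
    """Linear-in-time interpolation of sparse (e.g. fortnightly) REW to daily."""
    s = series.sort_index()
    idx = pd.date_range(s.index[0], s.index[-1], freq=freq)
    return s.reindex(s.index.union(idx)).interpolate(method="time").reindex(idx)


def cross_calibrate_sensor(sensor_readings, reference_readings):
    """OLS map from sensor units to reference units (e.g. capacitance probe
    against neutron probe), as slope/intercept with fit diagnostics.

    Requires at least 3 pairs with non-zero sensor variance.
    """
    x = np.asarray(sensor_readings, dtype=float)
    y = np.asarray(reference_readings, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if x.size < 3:
        raise ValueError(f"need >= 3 paired observations, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("sensor readings have zero variance")
    fit = stats.linregress(x, y)
    return {
        "slope": float(fit.slope),
        "intercept": float(fit.intercept),
        "r2": float(fit.rvalue ** 2),
        "stderr": float(fit.stderr),
        "n": int(x.size),
    }
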