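"""YAML configuration handling with parameter provenance.

A run configuration may override any of the shipped defaults (site,
stand geometry, soil profile, model parameters, synthetic-generator
settings). Every model parameter in the resolved set is labelled
``published-default`` or ``user`` so run logs state where each value came from.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .constants import Site
from .model import ModelParams
from .sapflow import StandParams
from .soilwater import SoilLayer, SoilProfile
from .synthetic import SyntheticConfig

__all__ = ["load_config", "resolve", "ConfigError"]


class ConfigError(ValueError):
    """Configuration file violates the expected schema."""


_SECTIONS = {"site", "stand", "soil", "model", "synthetic"}


def load_config(path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"config file not found: {path}")
    with open(path) as fh:
        try:
            raw = yaml.safe_load(fh) or {}
        except yaml.YAMLError as exc:
            raise ConfigError(f"invalid YAML in {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    unknown = set(raw) - _SECTIONS
    if unknown:
        raise ConfigError(
            f"unknown config section(s) {sorted(unknown)}; "
            f"expected a subset of {sorted(_SECTIONS)}")
    return raw


def _build(cls, section: dict | None, name: str):
    section = section or {}
    if not isinstance(section, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    valid = {f for f in cls.__dataclass_fields__}
    unknown = set(section) - valid
    if unknown:
        raise ConfigError(
            f"unknown key(s) in section {name!r}: {sorted(unknown)}")
    try:
        obj = cls(**section)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid section {name!r}: {exc}") from exc
    provenance = {f: ("user" if f in section else "published-default")
                  for f in valid}
    return obj, provenance


def _build_soil(section, name="soil"):
    if section is None:
        return SoilProfile(), {"layers": "published-default"}
    if not isinstance(section, dict) or "layers" not in section:
        raise ConfigError("section 'soil' must contain a 'layers' list")
    layers = []
    for i, spec in enumerate(section["layers"]):
        try:
            layers.append(SoilLayer(**spec))
        except (TypeError, ValueError) as exc:
            raise ConfigError(f"invalid soil layer {i}: {exc}") from exc
    try:
        return SoilProfile(tuple(layers)), {"layers": "user"}
    except ValueError as exc:
        raise ConfigError(f"invalid soil profile: {exc}") from exc


def resolve(raw: dict | None) -> dict:
    """Resolve a raw config mapping into typed objects plus provenance."""
    raw = raw or {}
    site, p_site = _build(Site, raw.get("site"), "site")
    stand_sec = dict(raw.get("stand") or {})
    if "spacing_m" in stand_sec:
        stand_sec["spacing_m"] = tuple(stand_sec["spacing_m"])
    stand, p_stand = _build(StandParams, stand_sec, "stand")
    soil, p_soil = _build_soil(raw.get("soil"))
    params, p_model = _build(ModelParams, raw.get("model"), "model")
    synth_sec = dict(raw.get("synthetic") or {})
    if "params" in synth_sec:
        synth_sec["params"] = ModelParams(**synth_sec["params"])
    synth, p_synth = _build(SyntheticConfig, synth_sec, "synthetic")
    return {
        "site": site, "stand": stand, "soil": soil,
        "model": params, "synthetic": synth,
        "provenance": {"site": p_site, "stand": p_stand, "soil": p_soil,
                       "model": p_model, "synthetic": p_synth},
    }
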