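"""Flat key/value configuration mirroring every tunable default.

The config file is YAML with a single flat mapping; unknown keys raise, so
typos are caught. ``default_config()`` is the authoritative list of
tunables; the CLI loads overrides with ``load_config``.
"""

from __future__ import annotations

from dataclasses import fields
from pathlib import Path

import yaml

from .circuit import CircuitParams
from .events import EIConfig
from .lfp import LfpConfig
from .spikes import SpikeConfig
from .synth import PopulationParams

__all__ = ["default_config", "load_config", "build"]

_SECTIONS = {
    "population": PopulationParams,
    "lfp": LfpConfig,
    "spikes": SpikeConfig,
    "events": EIConfig,
    "circuit": CircuitParams,
}


def _flat_defaults(prefix: str, cls) -> dict:
    return {f"{prefix}.{f.name}": getattr(cls(), f.name) for f in fields(cls)}


def default_config() -> dict:
    """Every tunable default, as flat dotted keys."""
    out: dict = {}
    for prefix, cls in _SECTIONS.items():
        out.update(_flat_defaults(prefix, cls))
    return out


def load_config(path: str | Path | None) -> dict:
    """Defaults overlaid with a flat YAML mapping; unknown keys raise."""
    cfg = default_config()
    if path is None:
        return cfg
    raw = yaml.safe_load(Path(path).read_text()) or {}
    for key, value in raw.items():
        if key not in cfg:
            raise KeyError(f"unknown config key {key!r}")
        if isinstance(cfg[key], tuple) and isinstance(value, list):
            value = tuple(value)
        cfg[key] = value
    return cfg


def build(cfg: dict, section: str, **overrides):
    """Instantiate a section's dataclass from a flat config dict."""
    cls = _SECTIONS[section]
    kwargs = {f.name: cfg[f"{section}.{f.name}"] for f in fields(cls)}
    kwargs.update(overrides)
    return cls(**kwargs)
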