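"""YAML configuration loading with strict key checking.

Configs are plain nested dataclasses; any key in a YAML file that does
not correspond to a dataclass field raises :class:`ConfigError` naming
the key, so typos fail loudly instead of silently using a default.
Precedence at the CLI is flags > file > defaults.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields, is_dataclass
from pathlib import Path

import yaml

from .errors import ConfigError
from .simulate import SimConfig
from .solar import SiteLocation

__all__ = ["PipelineConfig", "from_dict", "load_yaml", "load_sim_config", "load_pipeline_config"]


@dataclass
class PipelineConfig:
    """Configuration of the index + trend workflow."""

    loggers: str | None = None
    sensors: str | None = None
    masks: str | None = None
    reference: str | None = None  # optional daily reference radiation CSV
    outdir: str = "."
    site: SiteLocation = field(
        default_factory=lambda: SiteLocation(latitude=53.246, longitude=-9.221, utc_offset=0.0)
    )
    interval: str = "30min"
    tolerance: str = "5min"
    light_threshold: float = 0.0
    crepuscular_fraction: float = 0.1
    span: float = 0.4
    degree: int = 1
    robustness: int = 0
    k_a: float | None = 0.7
    aggregate: str = "points"  # or "daily-median"

    def __post_init__(self) -> None:
        if not 0 < self.span <= 1:
            raise ConfigError(f"span must be in (0, 1], got {self.span!r}")
        if not 0 <= self.crepuscular_fraction < 0.5:
            raise ConfigError(
                f"crepuscular_fraction must be in [0, 0.5), got {self.crepuscular_fraction!r}"
            )


def from_dict(cls, data: dict, context: str = ""):
    """Build a dataclass from a nested dict, rejecting unknown keys."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping for {cls.__name__}, got {type(data).__name__}")
    known = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in known:
            where = f" in {context}" if context else ""
            raise ConfigError(f"unknown config key {key!r}{where} (valid: {sorted(known)})")
        target = _nested_dataclass(cls, key)
        if target is not None and isinstance(value, dict):
            value = from_dict(target, value, context=key)
        kwargs[key] = value
    return cls(**kwargs)


def _nested_dataclass(cls, key):
    for f in fields(cls):
        if f.name == key:
            default = f.default_factory() if f.default_factory is not dataclasses.MISSING else f.default
            if is_dataclass(default):
                return type(default)
    return None


def load_yaml(path) -> dict:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level of a config file must be a mapping")
    return data


def load_sim_config(path=None, overrides: dict | None = None) -> SimConfig:
    data = load_yaml(path) if path else {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return from_dict(SimConfig, data)


def load_pipeline_config(path=None, overrides: dict | None = None) -> PipelineConfig:
    data = load_yaml(path) if path else {}
    if overrides:
        data.update({k: v for k, v in overrides.items() if v is not None})
    return from_dict(PipelineConfig, data)
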