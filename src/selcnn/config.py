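"""Run configuration: a YAML schema mirroring every tunable distribution.

Defaults reproduce the baseline study conditions (8 taxa, divergence 0.2,
indel rate 0.1, gene-class mix 40/10/50, decision threshold 0.5).  Unknown
keys raise a ConfigError naming the offending key, so typos fail loudly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .classifier import ModelSpec
from .simulate import SimulationConfig


class ConfigError(ValueError):
    pass


@dataclass
class EvaluationConfig:
    threshold: float = 0.5


@dataclass
class RunConfig:
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    training: ModelSpec = field(default_factory=ModelSpec)
    evaluation: EvaluationConfig = field(default_factory=EvaluationConfig)
    n_genes: int = 200
    n_test_genes: int = 0
    seed: int = 0
    shuffle_rows: bool = False
    log_level: str = "INFO"


def _build(cls, data: dict, context: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {context!r} must be a mapping")
    allowed = {f.name: f for f in fields(cls)}
    kwargs = {}
    for key, value in data.items():
        if key not in allowed:
            raise ConfigError(f"unknown config key {context}.{key}")
        ftype = allowed[key].type
        if isinstance(value, list) and "tuple" in str(ftype):
            value = tuple(value)
        kwargs[key] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid values in section {context!r}: {exc}") from exc


_SECTIONS = {
    "simulation": SimulationConfig,
    "training": ModelSpec,
    "evaluation": EvaluationConfig,
}


def load_config(path: str | Path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a YAML mapping")
    top_fields = {f.name for f in fields(RunConfig)}
    kwargs = {}
    for key, value in raw.items():
        if key not in top_fields:
            raise ConfigError(f"unknown config key {key}")
        if key in _SECTIONS:
            kwargs[key] = _build(_SECTIONS[key], value or {}, key)
        else:
            kwargs[key] = value
    try:
        return RunConfig(**kwargs)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid configuration: {exc}") from exc


def resolved_snapshot(config: RunConfig) -> str:
    """YAML snapshot of the fully resolved configuration for provenance."""

    def clean(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: clean(getattr(obj, f.name)) for f in fields(obj)}
        if isinstance(obj, tuple):
            return list(obj)
        if hasattr(obj, "tolist"):
            return obj.tolist()
        return obj

    return yaml.safe_dump(clean(config), sort_keys=False)
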