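"""Run configuration: a strict YAML-backed bundle of every pipeline threshold."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .synthdata import (
    BoutModelConfig,
    KernelConfig,
    NoiseConfig,
    PEModelConfig,
    SimConfig,
)

__all__ = ["RunConfig", "ConfigError", "load_config", "save_config"]


class ConfigError(ValueError):
    pass


@dataclass
class PreprocessConfig:
    target_fs: float | None = None
    line_base_hz: float = 50.0
    max_duration_s: float | None = 6 * 3600.0
    all_channels_mode: bool = False


@dataclass
class BehaviorConfig:
    bin_s: float = 1.0
    min_sleep_s: float = 300.0
    movement_threshold: float | None = None  # None: derived from a low quantile
    pe_threshold: float = 0.3
    pe_merge_gap_s: float = 0.1
    spell_gap_s: float = 5.0
    min_spell_events: int = 3
    reach_min_duration_s: float = 1.5
    pe_guard_s: float = 0.05


@dataclass
class SSVEPConfig:
    window_start_s: float = 0.0
    window_end_s: float = 0.1


@dataclass
class StatsConfig:
    alpha: float = 0.05


@dataclass
class ContrastSpec:
    name: str
    color: str | None = None
    role: str | None = None
    region: str | None = None


def _default_contrasts() -> list:
    return [
        ContrastSpec("carrier_vs_deviant", color="green", region="central"),
        ContrastSpec("wake_vs_sleep", role="carrier", color="green", region="central"),
        ContrastSpec("wake_vs_sleep", role="deviant", color="green", region="central"),
    ]


@dataclass
class RunConfig:
    # overnight-style runs are simulated and analyzed at the 200 Hz
    # long-recording rate; raise simulator.fs for acquisition-rate studies
    simulator: SimConfig = field(default_factory=lambda: SimConfig(fs=200.0))
    preprocessing: PreprocessConfig = field(default_factory=PreprocessConfig)
    behavior: BehaviorConfig = field(default_factory=BehaviorConfig)
    ssvep: SSVEPConfig = field(default_factory=SSVEPConfig)
    stats: StatsConfig = field(default_factory=StatsConfig)
    contrasts: list = field(default_factory=_default_contrasts)
    n_flies: int = 8
    duration_s: float = 2 * 3600.0
    trial_type: str = "phasic"
    seed: int = 0
    out_dir: str = "report"


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section '{path}' must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(f"unknown keys in '{path}': {sorted(unknown)}")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = {
            "simulator": SimConfig, "preprocessing": PreprocessConfig,
            "behavior": BehaviorConfig, "ssvep": SSVEPConfig, "stats": StatsConfig,
            "kernel": KernelConfig, "noise": NoiseConfig,
            "bout_model": BoutModelConfig, "pe_model": PEModelConfig,
        }.get(name)
        if sub is not None and isinstance(value, dict):
            kwargs[name] = _build(sub, value, f"{path}.{name}")
        elif name == "contrasts":
            kwargs[name] = [_build(ContrastSpec, c, f"{path}.contrasts[]") for c in value]
        elif name == "gains" and isinstance(value, dict):
            kwargs[name] = {
                tuple(k.split("|")) if isinstance(k, str) else tuple(k): v
                for k, v in value.items()
            }
        elif name == "events_per_spell" and isinstance(value, list):
            kwargs[name] = tuple(value)
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - guarded by unknown-key check
        raise ConfigError(str(exc)) from exc


def load_config(path) -> RunConfig:
    """Load and validate a YAML run configuration (unknown keys rejected)."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return _build(RunConfig, data, "run")


def save_config(config: RunConfig, path) -> None:
    def enc(obj):
        if dataclasses.is_dataclass(obj):
            return {f.name: enc(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
        if isinstance(obj, dict):
            return {("|".join(k) if isinstance(k, tuple) else k): enc(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [enc(v) for v in obj]
        return obj

    Path(path).write_text(yaml.safe_dump(enc(config)))
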