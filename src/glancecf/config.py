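"""Run configuration: YAML/JSON round-trip with schema validation.

A run configuration has three blocks: ``driver`` (all driver parameters),
``protocol`` (leader speed protocol) and ``simulation`` (timestep,
particle count, seed, initial conditions).  Unknown keys are rejected so
typos fail loudly; every omitted key falls back to the package default.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .environment import (DEFAULT_RAMP, DEFAULT_SWITCH_INTERVAL,
                          DEFAULT_TARGETS_KMH, REAL_CAR_DURATION,
                          SimulationConfig)
from .params import (AttentionParams, DriverParams, IDMParams,
                     PerceptionParams, PredictionParams)

__all__ = ["ProtocolConfig", "RunConfig", "load_config"]


class ConfigError(ValueError):
    """Malformed or unknown configuration content."""


@dataclass(frozen=True)
class ProtocolConfig:
    """Leader protocol block."""

    protocol: str = "vr"
    targets_kmh: tuple = DEFAULT_TARGETS_KMH
    switch_interval: tuple = DEFAULT_SWITCH_INTERVAL
    ramp_accel: float = DEFAULT_RAMP
    duration: float = REAL_CAR_DURATION


@dataclass(frozen=True)
class RunConfig:
    """Complete configuration of a simulation run."""

    driver: DriverParams = field(default_factory=DriverParams)
    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    simulation: SimulationConfig = field(default_factory=SimulationConfig)
    seed: int | None = None

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data or {})
        driver = _build_driver(data.pop("driver", {}))
        protocol = _build(ProtocolConfig, data.pop("protocol", {}),
                          "protocol", coerce_tuples=("targets_kmh",
                                                     "switch_interval"))
        simulation = _build(SimulationConfig, data.pop("simulation", {}),
                            "simulation",
                            coerce_tuples=("init_d_range", "init_r_range"))
        seed = data.pop("seed", None)
        if data:
            raise ConfigError(f"unknown top-level keys: {sorted(data)}")
        cfg = cls(driver=driver, protocol=protocol, simulation=simulation,
                  seed=seed)
        cfg.driver.validate()
        return cfg

    def to_dict(self) -> dict:
        return {
            "driver": dataclasses.asdict(self.driver),
            "protocol": _plain(dataclasses.asdict(self.protocol)),
            "simulation": _plain(dataclasses.asdict(self.simulation)),
            "seed": self.seed,
        }

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(),
                                             sort_keys=False))


def _plain(d: dict) -> dict:
    return {k: list(v) if isinstance(v, tuple) else v for k, v in d.items()}


def _build(cls, data: dict, name: str, coerce_tuples=()):
    if not isinstance(data, dict):
        raise ConfigError(f"{name} block must be a mapping")
    data = dict(data)
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(f"unknown keys in {name} block: {sorted(unknown)}")
    for key in coerce_tuples:
        if key in data:
            data[key] = tuple(data[key])
    return cls(**data)


def _build_driver(data: dict) -> DriverParams:
    if not isinstance(data, dict):
        raise ConfigError("driver block must be a mapping")
    data = dict(data)
    sub = {
        "perception": _build(PerceptionParams, data.pop("perception", {}),
                             "driver.perception"),
        "prediction": _build(PredictionParams, data.pop("prediction", {}),
                             "driver.prediction"),
        "idm": _build(IDMParams, data.pop("idm", {}), "driver.idm"),
        "attention": _build(AttentionParams, data.pop("attention", {}),
                            "driver.attention"),
    }
    if data:
        raise ConfigError(f"unknown keys in driver block: {sorted(data)}")
    return DriverParams(**sub)


def load_config(path) -> RunConfig:
    """Load a YAML or JSON run configuration file."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text)
    else:
        data = yaml.safe_load(text)
    return RunConfig.from_dict(data or {})
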