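"""Experiment configuration: the full parameter ledger for a pipeline run.

Defaults follow the published workflow: notch filtering at 50 and 100 Hz,
16 s analysis windows, simplification with a 50-sample rolling median and
decimation by 10, per-window min-max normalization, the attention encoder
architecture, and causal confidence fusion.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any

import yaml

__all__ = [
    "ConfigError",
    "SimplifyParams",
    "FusionParams",
    "TrainBudget",
    "ProtocolParams",
    "ExperimentConfig",
    "load_config",
]

NORMALIZATION_MODES = ("none", "per_plant_minmax", "per_window_minmax", "per_window_demean")
ARCHITECTURES = ("mlp", "fcn", "resnet", "encoder")
FUSION_METHODS = ("mean", "median")
PROTOCOL_MODES = ("post_symptom", "extended")


class ConfigError(ValueError):
    """Raised when a configuration violates an invariant; names the field."""


@dataclasses.dataclass
class SimplifyParams:
    S: float = 16.0       # window length, seconds
    N: int = 50           # rolling-median width, samples
    F: int = 10           # decimation factor

    def validate(self) -> None:
        if self.S <= 0:
            raise ConfigError(f"simplify.S must be positive, got {self.S}")
        if self.N < 1:
            raise ConfigError(f"simplify.N must be >= 1, got {self.N}")
        if self.F < 1:
            raise ConfigError(f"simplify.F must be >= 1, got {self.F}")


@dataclasses.dataclass
class FusionParams:
    L: int = 10
    method: str = "mean"

    def validate(self) -> None:
        if self.L < 1:
            raise ConfigError(f"fusion.L must be >= 1, got {self.L}")
        if self.method not in FUSION_METHODS:
            raise ConfigError(f"fusion.method must be one of {FUSION_METHODS}, got {self.method!r}")


@dataclasses.dataclass
class TrainBudget:
    epochs: int = 10
    max_seconds: float | None = None

    def validate(self) -> None:
        if self.epochs < 0:
            raise ConfigError(f"train_budget.epochs must be >= 0, got {self.epochs}")


@dataclasses.dataclass
class ProtocolParams:
    train_hours_per_state: float = 48.0
    mode: str = "post_symptom"
    test_plants: list[str] = dataclasses.field(default_factory=lambda: ["B0", "B5", "C5"])

    def validate(self) -> None:
        if self.train_hours_per_state <= 0:
            raise ConfigError(
                "protocol.train_hours_per_state must be positive, "
                f"got {self.train_hours_per_state}"
            )
        if self.mode not in PROTOCOL_MODES:
            raise ConfigError(f"protocol.mode must be one of {PROTOCOL_MODES}, got {self.mode!r}")


@dataclasses.dataclass
class ExperimentConfig:
    notch_freqs: list[float] = dataclasses.field(default_factory=lambda: [50.0, 100.0])
    window_length_s: float = 16.0
    simplify: SimplifyParams = dataclasses.field(default_factory=SimplifyParams)
    normalization: str = "per_window_minmax"
    architecture: str = "encoder"
    train_budget: TrainBudget = dataclasses.field(default_factory=TrainBudget)
    fusion: FusionParams = dataclasses.field(default_factory=FusionParams)
    decision_threshold: float = 0.5
    onset_threshold: float = 0.65
    protocol: ProtocolParams = dataclasses.field(default_factory=ProtocolParams)
    seed: int = 0

    def validate(self) -> "ExperimentConfig":
        self.simplify.validate()
        self.fusion.validate()
        self.train_budget.validate()
        self.protocol.validate()
        if self.window_length_s <= 0:
            raise ConfigError(f"window_length_s must be positive, got {self.window_length_s}")
        if not (0 < self.decision_threshold < 1):
            raise ConfigError(
                f"decision_threshold must lie in (0, 1), got {self.decision_threshold}"
            )
        if not (0.5 < self.onset_threshold < 1):
            raise ConfigError(
                f"onset_threshold must lie in (0.5, 1), got {self.onset_threshold}"
            )
        if self.normalization not in NORMALIZATION_MODES:
            raise ConfigError(
                f"normalization must be one of {NORMALIZATION_MODES}, got {self.normalization!r}"
            )
        if self.architecture not in ARCHITECTURES:
            raise ConfigError(
                f"architecture must be one of {ARCHITECTURES}, got {self.architecture!r}"
            )
        for f in self.notch_freqs:
            if f <= 0:
                raise ConfigError(f"notch_freqs entries must be positive, got {f}")
        return self


def _build_nested(cls: type, data: dict[str, Any]) -> Any:
    fields = {f.name: f for f in dataclasses.fields(cls)}
    kwargs: dict[str, Any] = {}
    for key, value in data.items():
        if key not in fields:
            raise ConfigError(f"unknown configuration field {key!r} for {cls.__name__}")
        nested = {"simplify": SimplifyParams, "fusion": FusionParams,
                  "train_budget": TrainBudget, "protocol": ProtocolParams}.get(key)
        if nested is not None and isinstance(value, dict):
            kwargs[key] = _build_nested(nested, value)
        else:
            kwargs[key] = value
    return cls(**kwargs)


def load_config(path: str | Path | None = None, overrides: dict[str, Any] | None = None) -> ExperimentConfig:
    """Load a YAML config; unspecified fields take documented defaults."""
    data: dict[str, Any] = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ConfigError(f"config file {path} must hold a YAML mapping")
        data.update(raw)
    if overrides:
        data.update(overrides)
    cfg = _build_nested(ExperimentConfig, data)
    return cfg.validate()
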