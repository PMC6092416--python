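"""YAML configuration loading for the CLI and the experiment driver."""

from __future__ import annotations

import dataclasses
import os

import yaml

from .candidate_detection import DetectConfig
from .experiment import ExperimentConfig


class ConfigError(ValueError):
    """Raised when a YAML config contains unknown or ill-typed keys."""


def _build(cls, data: dict, context: str):
    valid = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - valid
    if unknown:
        raise ConfigError(f"unknown keys in {context} config: {sorted(unknown)}")
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if isinstance(v, list):
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def load_experiment_config(path: str | os.PathLike | None) -> ExperimentConfig:
    """Load an :class:`ExperimentConfig` from YAML (``detect:`` nests a DetectConfig)."""
    if path is None:
        return ExperimentConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"experiment config {path!r} must be a mapping")
    detect = data.pop("detect", {})
    cfg = _build(ExperimentConfig, data, "experiment")
    cfg.detect = _build(DetectConfig, detect or {}, "detect")
    return cfg


def load_detect_config(path: str | os.PathLike | None) -> DetectConfig:
    if path is None:
        return DetectConfig()
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"detect config {path!r} must be a mapping")
    return _build(DetectConfig, data.get("detect", data), "detect")
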