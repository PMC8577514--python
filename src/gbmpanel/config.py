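"""YAML loading for the stage and pipeline config dataclasses."""

from __future__ import annotations

import dataclasses
import typing
from pathlib import Path

import yaml

from .booster import BoosterConfig
from .consensus import ConsensusConfig
from .errors import ValidationError
from .pipeline import PipelineConfig
from .preprocess import NormalizationConfig
from .selection import SelectionConfig
from .simulate import SimulationSpec

_NESTED = {
    "simulation": SimulationSpec,
    "normalization": NormalizationConfig,
    "selection": SelectionConfig,
    "consensus": ConsensusConfig,
    "base": BoosterConfig,
}

_TUPLE_FIELDS = {"samples_per_class", "baseline_log_mean_range", "class_names"}


def _from_dict(cls, data: dict):
    if data is None:
        return None
    if not isinstance(data, dict):
        raise ValidationError(f"expected a mapping for {cls.__name__}, got {data!r}")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValidationError(
            f"unknown {cls.__name__} fields: {sorted(unknown)}"
        )
    kwargs = {}
    for key, value in data.items():
        if key in _NESTED and isinstance(value, dict) or (
            key == "simulation" and value is None
        ):
            value = _from_dict(_NESTED[key], value)
        elif key in _TUPLE_FIELDS and isinstance(value, (list, tuple)):
            value = tuple(value)
        kwargs[key] = value
    return cls(**kwargs)


def simulation_spec_from_dict(data: dict) -> SimulationSpec:
    return _from_dict(SimulationSpec, data)


def pipeline_config_from_dict(data: dict) -> PipelineConfig:
    return _from_dict(PipelineConfig, data or {})


def load_yaml(path: str | Path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ValidationError(f"{path} must contain a YAML mapping")
    return doc


def simulation_spec_from_yaml(path: str | Path) -> SimulationSpec:
    return simulation_spec_from_dict(load_yaml(path))


def pipeline_config_from_yaml(path: str | Path) -> PipelineConfig:
    return pipeline_config_from_dict(load_yaml(path))


def selection_config_from_yaml(path: str | Path) -> SelectionConfig:
    return _from_dict(SelectionConfig, load_yaml(path))


def consensus_config_from_yaml(path: str | Path) -> ConsensusConfig:
    return _from_dict(ConsensusConfig, load_yaml(path))
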