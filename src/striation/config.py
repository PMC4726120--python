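"""YAML configuration loading with strict schema checking."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, TypeVar

import yaml

from .pipeline import AnalysisConfig
from .segmentation import SegmentationConfig
from .synth import SceneConfig

__all__ = [
    "ConfigError",
    "load_yaml",
    "scene_config_from_dict",
    "analysis_config_from_dict",
]

T = TypeVar("T")


class ConfigError(ValueError):
    """Invalid or unknown configuration field."""


def load_yaml(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return {}
    if not isinstance(data, dict):
        raise ConfigError(f"top level of {path} must be a mapping")
    return data


def _coerce_tuples(cls: type, kwargs: dict) -> dict:
    # YAML lists become tuples where the dataclass default is a tuple.
    out = dict(kwargs)
    for f in dataclasses.fields(cls):
        if f.name in out and isinstance(out[f.name], list):
            out[f.name] = tuple(
                tuple(v) if isinstance(v, list) else v for v in out[f.name]
            )
    return out


def _build(cls: type[T], data: dict, context: str) -> T:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(
            f"unknown field(s) in {context}: {', '.join(sorted(unknown))}"
        )
    try:
        return cls(**_coerce_tuples(cls, data))
    except (TypeError, ValueError) as e:
        raise ConfigError(f"invalid {context}: {e}") from e


def scene_config_from_dict(data: dict) -> SceneConfig:
    return _build(SceneConfig, data, "scene config")


def analysis_config_from_dict(data: dict) -> AnalysisConfig:
    data = dict(data)
    seg = data.pop("segmentation", None)
    cfg_kwargs: dict[str, Any] = data
    if seg is not None:
        if not isinstance(seg, dict):
            raise ConfigError("'segmentation' must be a mapping")
        cfg_kwargs["segmentation"] = _build(
            SegmentationConfig, seg, "segmentation config"
        )
    return _build(AnalysisConfig, cfg_kwargs, "analysis config")
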