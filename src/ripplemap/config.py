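"""YAML (de)serialization for parameter dataclasses."""

from __future__ import annotations

import dataclasses
from pathlib import Path
from typing import Any, TypeVar

import yaml

from .detection import DetectionParams
from .synthetic import GeneratorConfig, RegionModulation

T = TypeVar("T")


def to_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {f.name: to_dict(getattr(obj, f.name)) for f in dataclasses.fields(obj)}
    if isinstance(obj, dict):
        return {k: to_dict(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [to_dict(v) for v in obj]
    if hasattr(obj, "item"):  # numpy scalar
        return obj.item()
    return obj


def _build(cls: type[T], data: dict) -> T:
    kwargs = {}
    for f in dataclasses.fields(cls):
        if f.name not in data:
            continue
        v = data[f.name]
        if f.name == "region_modulation":
            v = {k: RegionModulation(**rm) if isinstance(rm, dict) else rm for k, rm in v.items()}
        elif f.name in ("seed_probs_common", "seed_probs_strong") and v is not None:
            v = tuple(v)
        kwargs[f.name] = v
    return cls(**kwargs)


def detection_params_from_dict(data: dict) -> DetectionParams:
    return _build(DetectionParams, data)


def generator_config_from_dict(data: dict) -> GeneratorConfig:
    return _build(GeneratorConfig, data)


def save_yaml(obj: Any, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(yaml.safe_dump(to_dict(obj), sort_keys=True))
    return path


def load_yaml(path: str | Path) -> dict:
    return yaml.safe_load(Path(path).read_text()) or {}
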