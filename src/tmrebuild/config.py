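"""YAML configuration loading for the modeling pipeline."""

from __future__ import annotations

from dataclasses import asdict, fields

import yaml

from .pipeline import PipelineConfig
from .sampler import MoveSet, EnergyWeights
from .refine import RefineSchedule

_NESTED = {"moves": MoveSet, "weights": EnergyWeights,
           "refine": RefineSchedule}


def config_to_dict(cfg: PipelineConfig) -> dict:
    out = asdict(cfg)
    for key in _NESTED:
        out[key] = dict(out[key])
        for k, v in out[key].items():
            if isinstance(v, tuple):
                out[key][k] = list(v)
    return out


def config_from_dict(data: dict) -> PipelineConfig:
    data = dict(data or {})
    kwargs = {}
    for key, cls in _NESTED.items():
        if key in data:
            sub = data.pop(key)
            names = {f.name for f in fields(cls)}
            unknown = set(sub) - names
            if unknown:
                raise ValueError(f"unknown {key} options: {sorted(unknown)}")
            sub = {k: (tuple(v) if isinstance(v, list) else v)
                   for k, v in sub.items()}
            kwargs[key] = cls(**sub)
    names = {f.name for f in fields(PipelineConfig)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config options: {sorted(unknown)}")
    return PipelineConfig(**kwargs, **data)


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        return config_from_dict(yaml.safe_load(fh))


def save_config(cfg: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)
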