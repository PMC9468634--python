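"""Experiment configuration as YAML.

One document with optional sections ``simulate``, ``augment``, ``encoder``,
``pretrain`` and ``finetune``; omitted keys fall back to the dataclass
defaults (which are the operative hyperparameters of the method).
"""

from __future__ import annotations

import math
from dataclasses import asdict, fields
from pathlib import Path

import yaml

from .augment import AugmentPolicy
from .cssl import PretrainConfig
from .downstream import FinetuneConfig
from .encoder import EncoderConfig
from .synthetic_data import SimulationConfig

_SECTIONS = {
    "simulate": SimulationConfig,
    "augment": AugmentPolicy,
    "encoder": EncoderConfig,
    "pretrain": PretrainConfig,
    "finetune": FinetuneConfig,
}


def _coerce(cls, raw: dict):
    known = {f.name for f in fields(cls)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    kwargs = {}
    for k, v in raw.items():
        if isinstance(v, list):
            v = tuple(v)
        if isinstance(v, str) and v.lower() in ("inf", "infinity"):
            v = math.inf
        kwargs[k] = v
    return cls(**kwargs)


def load_experiment(path: str | Path) -> dict:
    """Parse an experiment YAML into dataclass instances per section."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    unknown = set(raw) - set(_SECTIONS)
    if unknown:
        raise ValueError(f"unknown config sections: {sorted(unknown)}")
    return {name: _coerce(cls, raw.get(name) or {}) for name, cls in _SECTIONS.items()}


def default_experiment() -> dict:
    return {name: cls() for name, cls in _SECTIONS.items()}


def dump_experiment(cfgs: dict, path: str | Path) -> None:
    doc = {}
    for name, cfg in cfgs.items():
        d = asdict(cfg)
        doc[name] = {
            k: ("inf" if isinstance(v, float) and math.isinf(v) else
                list(v) if isinstance(v, tuple) else v)
            for k, v in d.items()
        }
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))
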