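"""Experiment configuration: defaults, YAML loading, hashing, seed splitting."""

from __future__ import annotations

import dataclasses
import hashlib
import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import yaml

from .circuit import FitConfig
from .rnn import TrainConfig

__all__ = [
    "TaskConfig",
    "ExperimentConfig",
    "load_config",
    "save_config",
    "split_seed",
]


@dataclass
class TaskConfig:
    dt_ms: float = 40.0
    trial_ms: float = 3000.0
    sigma_in: float = 0.01
    baseline: float = 0.2


@dataclass
class RNNConfig:
    N: int = 50
    tau: float = 200.0
    dt: float = 40.0
    sigma_rec: float = 0.15
    frac_exc: float = 0.8


@dataclass
class ExperimentConfig:
    task: TaskConfig = field(default_factory=TaskConfig)
    rnn: RNNConfig = field(default_factory=RNNConfig)
    train: TrainConfig = field(default_factory=TrainConfig)
    fit: FitConfig = field(default_factory=FitConfig)
    seed: int = 0
    out_dir: str = "runs"

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)

    def content_hash(self) -> str:
        blob = json.dumps(self.as_dict(), sort_keys=True, default=float)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        sub = _SECTIONS.get((cls, name))
        if sub is not None:
            if not isinstance(value, dict):
                raise ValueError(f"'{path}{name}' must be a mapping")
            kwargs[name] = _build(sub, value, f"{path}{name}.")
        else:
            kwargs[name] = tuple(value) if isinstance(value, list) else value
    return cls(**kwargs)


_SECTIONS = {
    (ExperimentConfig, "task"): TaskConfig,
    (ExperimentConfig, "rnn"): RNNConfig,
    (ExperimentConfig, "train"): TrainConfig,
    (ExperimentConfig, "fit"): FitConfig,
}


def load_config(path) -> ExperimentConfig:
    """Load a YAML experiment config; missing keys take the standard
    defaults (tau = 200 ms, dt = 40 ms, sigma_rec = 0.15, ...), unknown
    keys are rejected with the offending name."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    return _build(ExperimentConfig, data, "")


def save_config(cfg: ExperimentConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.as_dict(), fh, sort_keys=True)


def split_seed(seed: int, label: str) -> int:
    """Deterministically derive a component seed (< 2^31) from a global seed
    and a component label."""
    tag = zlib.crc32(label.encode())
    return int(np.random.SeedSequence([seed, tag]).generate_state(1)[0] % 2**31)
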