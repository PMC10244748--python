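"""Experiment configuration records, loadable from YAML or JSON."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["SingleNeuronConfig", "TrainConfig", "SurpriseConfig", "CorrelationConfig", "load_config"]


def _from_file(cls, path, **overrides):
    data = {}
    if path is not None:
        text = Path(path).read_text()
        data = yaml.safe_load(text) if str(path).endswith((".yml", ".yaml")) else json.loads(text)
        if data is None:
            data = {}
    data.update(overrides)
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ValueError(f"unknown config keys for {cls.__name__}: {sorted(unknown)}")
    return cls(**data)


@dataclass
class _Base:
    seed: int = 0

    @classmethod
    def from_file(cls, path=None, **overrides):
        return _from_file(cls, path, **overrides)

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


@dataclass
class SingleNeuronConfig(_Base):
    epochs: int = 60
    lr: float = 0.1
    duration: float = 10.0
    dt: float = 0.01
    k: float = 0.5
    alpha: float = 0.1
    tau_u: float = 1.0
    tol: float = 0.1


@dataclass
class TrainConfig(_Base):
    """Multilayer DH-DFC training on the Gaussian-blob task."""

    hidden: tuple = (16, 16)
    activation: str = "sigmoid"
    epochs: int = 30
    lr: float = 0.1
    lr_decay: float = 0.9
    lr_hold: int = 15
    init_gain: float = 3.0
    duration: float = 3.0
    dt: float = 0.02
    k: float = 0.5
    alpha: float = 0.1
    tau_u: float = 1.0
    tol: float = 0.1
    # Q pre-training
    beta: float = 0.01
    q_noise_sd: float = 1.0
    q_lr: float = 1.0
    q_episodes: int = 200
    # dataset
    n_classes: int = 4
    n_per_class: int = 25
    dim: int = 2
    sep: float = 6.0
    # optional IDX digit images instead of blobs
    idx_images: str | None = None
    idx_labels: str | None = None
    n_subset: int | None = None


@dataclass
class SurpriseConfig(TrainConfig):
    epochs: int = 42
    shuffle_epoch: int = 20


@dataclass
class CorrelationConfig(TrainConfig):
    mid_epochs: int = 5
    batch_size: int = 20
    stdp_realizations: int = 100


def load_config(cls, path=None, **overrides):
    """Load a config dataclass from a YAML/JSON file with overrides."""
    return _from_file(cls, path, **overrides)
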