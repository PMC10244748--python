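"""Desk-scale experiment drivers.

Thin functional wrappers over the Model/Results classes in
:mod:`dhlearn.models`, one per protocol: single-neuron supervision,
multilayer DH-DFC training, cross-rule update alignment, and the
label-shuffle ("surprise") run.  The CLI calls these.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .config import CorrelationConfig, SingleNeuronConfig, SurpriseConfig, TrainConfig
from .control import FeedbackTrainingConfig
from .datasets import Dataset, gaussian_blobs, read_idx_images, two_input_task
from .models import (
    DeepFeedbackModel,
    DeepFeedbackResults,
    PredictiveCodingModel,
    SingleNeuronModel,
    SingleNeuronResults,
)

__all__ = [
    "gen_two_input_task",
    "gen_gaussian_classification",
    "build_dataset",
    "run_single_neuron_experiment",
    "build_deep_feedback_model",
    "train_dh_dfc",
    "run_correlation_experiment",
    "run_surprise_experiment",
]

# dataset generators re-exported under the driver-facing names
gen_two_input_task = two_input_task
gen_gaussian_classification = gaussian_blobs


def build_dataset(cfg: TrainConfig) -> Dataset:
    """Gaussian blobs by default, or an IDX digit subset when configured."""
    if cfg.idx_images is not None:
        ds = read_idx_images(cfg.idx_images, cfg.idx_labels)
        if cfg.n_subset is not None:
            ds = ds.subset(np.arange(min(cfg.n_subset, len(ds))))
        return ds
    return gaussian_blobs(cfg.n_classes, cfg.n_per_class, cfg.dim, cfg.sep, seed=cfg.seed)


def run_single_neuron_experiment(cfg: SingleNeuronConfig | None = None) -> SingleNeuronResults:
    cfg = cfg if cfg is not None else SingleNeuronConfig()
    model = SingleNeuronModel(
        lr=cfg.lr, duration=cfg.duration, dt=cfg.dt,
        k=cfg.k, alpha=cfg.alpha, tau_u=cfg.tau_u, tol=cfg.tol,
    )
    return model.fit(epochs=cfg.epochs, seed=cfg.seed)


def build_deep_feedback_model(cfg: TrainConfig, dataset: Dataset | None = None) -> DeepFeedbackModel:
    dataset = dataset if dataset is not None else build_dataset(cfg)
    q_cfg = FeedbackTrainingConfig(
        beta=cfg.beta, noise_sd=cfg.q_noise_sd, lr_q=cfg.q_lr,
        n_episodes=cfg.q_episodes, duration=cfg.duration, dt=cfg.dt, seed=cfg.seed,
    )
    return DeepFeedbackModel(
        dataset, hidden=tuple(cfg.hidden), activation=cfg.activation,
        lr=cfg.lr, lr_decay=cfg.lr_decay, lr_hold=cfg.lr_hold,
        init_gain=cfg.init_gain, duration=cfg.duration, dt=cfg.dt,
        k=cfg.k, alpha=cfg.alpha, tau_u=cfg.tau_u, tol=cfg.tol,
        q_config=q_cfg, seed=cfg.seed,
    )


def train_dh_dfc(cfg: TrainConfig | None = None, dataset: Dataset | None = None) -> DeepFeedbackResults:
    cfg = cfg if cfg is not None else TrainConfig()
    return build_deep_feedback_model(cfg, dataset).fit(epochs=cfg.epochs)


def run_correlation_experiment(
    cfg: CorrelationConfig | None = None, dataset: Dataset | None = None
) -> pd.DataFrame:
    """Mid-training update alignment: R^2 of DH vs BP, delta, expected STDP."""
    cfg = cfg if cfg is not None else CorrelationConfig()
    model = build_deep_feedback_model(cfg, dataset)
    model.fit(epochs=cfg.mid_epochs)
    rng = np.random.default_rng(cfg.seed + 7)
    batch = rng.choice(len(model.dataset), size=min(cfg.batch_size, len(model.dataset)), replace=False)
    return model.update_alignment(batch, stdp_realizations=cfg.stdp_realizations, seed=cfg.seed)


def run_surprise_experiment(
    cfg: SurpriseConfig | None = None, dataset: Dataset | None = None
) -> DeepFeedbackResults:
    cfg = cfg if cfg is not None else SurpriseConfig()
    model = build_deep_feedback_model(cfg, dataset)
    return model.fit(epochs=cfg.epochs, shuffle_epoch=cfg.shuffle_epoch)


def run_pc_experiment(
    dataset: Dataset, rule: str = "hebbian_error", epochs: int = 30, seed: int = 0, **kwargs
):
    model = PredictiveCodingModel(dataset, rule=rule, seed=seed, **kwargs)
    return model.fit(epochs=epochs)
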