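"""Model/Results objects for the package's experiments.

Three fit-able models, each returning a Results object carrying the
trained network, a per-epoch history frame and a ``summary()`` table:

* :class:`SingleNeuronModel` — one sigmoid neuron with two fixed inputs,
  supervised through the PI controller, trained with the DH rule while
  a single-realization STDP update is logged for comparison.
* :class:`DeepFeedbackModel` — a multilayer network trained with
  DH updates under controller feedback (DH-DFC): anti-Hebbian Q
  pre-training, per-sample closed-loop trials, per-epoch L/H/T and
  classification error, optional label-shuffle ("surprise") protocol,
  and cross-rule update-alignment diagnostics.
* :class:`PredictiveCodingModel` — supervised PC trained with the
  Hebbian-error or DH rule.

Plotting hangs off the Results objects (matplotlib figures returned,
never shown).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .control import FeedbackTrainingConfig, PIController, run_closed_loop, train_feedback_weights
from .datasets import Dataset, one_hot_targets, two_input_task
from .metrics import feedback_cost, mse_loss, time_to_target
from .network import LayeredNetwork, feedforward_pass
from .pc import train_pc
from .plasticity import (
    UpdateSet,
    bp_update_reference,
    delta_update_from_trajectory,
    dh_update_from_trajectory,
    update_regression,
)
from .spiking import STDPKernel, rates_to_poisson_spikes, stdp_expected_update, stdp_pairwise_update

__all__ = [
    "SingleNeuronModel",
    "SingleNeuronResults",
    "DeepFeedbackModel",
    "DeepFeedbackResults",
    "PredictiveCodingModel",
    "PredictiveCodingResults",
]


def _controller(k: float, alpha: float, tau_u: float) -> PIController:
    return PIController(k=k, alpha=alpha, tau_u=tau_u)


def _censored(t: float, duration: float) -> float:
    """Censor a not-reached latency at the trial duration."""
    return min(t, duration)


# ===========================================================================
# Single neuron


class SingleNeuronModel:
    """Two-input single-neuron supervision with DH learning.

    Stimuli alternate: A (input rates (1, 0)) with target rate 0.05 and
    B ((0, 1)) with target 0.95.  Each presentation runs the closed loop
    from the open-loop equilibrium, applies the DH update scaled by
    ``lr``, and logs L, H, T plus the per-trial DH and single-spike-train
    STDP updates.
    """

    def __init__(
        self,
        w_init: Sequence[float] = (1.0, 1.0),
        lr: float = 0.1,
        duration: float = 10.0,
        dt: float = 0.01,
        k: float = 0.5,
        alpha: float = 0.1,
        tau_u: float = 1.0,
        tol: float = 0.1,
        kernel: STDPKernel | None = None,
    ) -> None:
        self.w_init = tuple(float(w) for w in w_init)
        self.lr = lr
        self.duration = duration
        self.dt = dt
        self.k, self.alpha, self.tau_u = k, alpha, tau_u
        self.tol = tol
        self.kernel = kernel if kernel is not None else STDPKernel()

    def _fresh_net(self) -> LayeredNetwork:
        return LayeredNetwork((2, 1), [np.array([list(self.w_init)])], np.array([[1.0]]), "sigmoid")

    def fit(self, epochs: int = 60, seed: int = 0) -> "SingleNeuronResults":
        net = self._fresh_net()
        stimuli = two_input_task()
        rng = np.random.default_rng(seed)
        rows = []
        for epoch in range(1, epochs + 1):
            rec = {"epoch": epoch, "w_A": net.W[0][0, 0], "w_B": net.W[0][0, 1]}
            Ls, Hs, Ts = [], [], []
            for name, (x, y) in zip("AB", stimuli):
                ctrl = _controller(self.k, self.alpha, self.tau_u)
                traj = run_closed_loop(net, x, y, ctrl, self.duration, self.dt)
                upd = dh_update_from_trajectory(traj, net)
                spikes = rates_to_poisson_spikes(traj, rng)
                # synapse (output <- input j); output neuron is the last train
                stdp = [
                    stdp_pairwise_update(spikes.trains[j], spikes.trains[2], self.kernel)
                    for j in range(2)
                ]
                rec[f"dh_A_{name}"], rec[f"dh_B_{name}"] = upd.deltas[0][0]
                rec[f"stdp_A_{name}"], rec[f"stdp_B_{name}"] = stdp
                Ls.append(mse_loss(traj, y))
                Hs.append(feedback_cost(traj))
                Ts.append(_censored(time_to_target(traj, self.tol), self.duration))
                net.W[0] += self.lr * upd.deltas[0]
            rec["L"], rec["H"], rec["T"] = np.mean(Ls), np.mean(Hs), np.mean(Ts)
            rows.append(rec)
        return SingleNeuronResults(self, net, pd.DataFrame(rows))


@dataclass
class SingleNeuronResults:
    model: SingleNeuronModel
    net: LayeredNetwork
    history: pd.DataFrame

    def dh_stdp_pairs(self) -> tuple[np.ndarray, np.ndarray]:
        """All per-trial (DH, STDP) update pairs over the run, flattened."""
        h = self.history
        dh = np.concatenate([h[c].to_numpy() for c in ("dh_A_A", "dh_B_A", "dh_A_B", "dh_B_B")])
        st = np.concatenate([h[c].to_numpy() for c in ("stdp_A_A", "stdp_B_A", "stdp_A_B", "stdp_B_B")])
        return dh, st

    def dh_stdp_correlation(self) -> float:
        """Pearson correlation between per-trial DH and STDP updates."""
        dh, st = self.dh_stdp_pairs()
        return float(np.corrcoef(dh, st)[0, 1])

    def summary(self) -> str:
        h = self.history
        first, last = h.iloc[0], h.iloc[-1]
        lines = [
            "Single-neuron DH supervision",
            "=" * 34,
            f"epochs                 {len(h)}",
            f"w_A  first -> last     {first.w_A:+.4f} -> {last.w_A:+.4f}",
            f"w_B  first -> last     {first.w_B:+.4f} -> {last.w_B:+.4f}",
            f"L    first -> last     {first.L:.4f} -> {last.L:.4f}",
            f"H    first -> last     {first.H:.4f} -> {last.H:.4f}",
            f"T    first -> last     {first['T']:.3f} -> {last['T']:.3f}",
            f"DH~STDP Pearson r      {self.dh_stdp_correlation():.3f}",
        ]
        return "\n".join(lines)

    def plot(self):
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(11, 3))
        h = self.history
        axes[0].plot(h.epoch, h.w_A, label="$w_A$")
        axes[0].plot(h.epoch, h.w_B, label="$w_B$")
        axes[0].set(xlabel="epoch", ylabel="weight")
        axes[0].legend()
        for col, ax in (("L", axes[1]), ("H", axes[1])):
            ax.plot(h.epoch, h[col], label=col)
        axes[1].set(xlabel="epoch", ylabel="loss")
        axes[1].legend()
        dh, st = self.dh_stdp_pairs()
        axes[2].scatter(dh, st, s=8, alpha=0.5)
        axes[2].set(xlabel="DH update", ylabel="STDP update")
        fig.tight_layout()
        return fig


# ===========================================================================
# Multilayer DH-DFC


class DeepFeedbackModel:
    """Multilayer classifier trained with DH updates under DFC feedback.

    The feedback matrix Q is pre-trained once with the noise-driven
    anti-Hebbian rule and then frozen; each training sample then runs a
    noise-free closed-loop trial (about ``duration/dt`` controller
    steps) from the open-loop equilibrium, and the DH update of the full
    trajectory is applied with learning rate ``lr``.  Classification is
    read out as the argmax of the open-loop output.
    """

    def __init__(
        self,
        dataset: Dataset,
        layer_sizes: Sequence[int] | None = None,
        hidden: Sequence[int] = (16, 16),
        activation: str = "sigmoid",
        lr: float = 0.1,
        lr_decay: float = 0.9,
        lr_hold: int = 15,
        init_gain: float = 3.0,
        duration: float = 3.0,
        dt: float = 0.02,
        k: float = 0.5,
        alpha: float = 0.1,
        tau_u: float = 1.0,
        tol: float = 0.1,
        q_config: FeedbackTrainingConfig | None = None,
        seed: int = 0,
    ) -> None:
        self.dataset = dataset
        n_in = dataset.X.shape[1]
        n_out = dataset.targets.shape[1]
        self.layer_sizes = tuple(layer_sizes) if layer_sizes is not None else (n_in, *hidden, n_out)
        if self.layer_sizes[0] != n_in or self.layer_sizes[-1] != n_out:
            raise ValueError("layer_sizes incompatible with dataset dimensions")
        self.activation = activation
        self.lr = lr
        self.lr_decay = lr_decay
        self.lr_hold = lr_hold
        self.duration, self.dt = duration, dt
        self.k, self.alpha, self.tau_u = k, alpha, tau_u
        self.tol = tol
        self.q_config = q_config if q_config is not None else FeedbackTrainingConfig()
        self.seed = seed
        # init gain > 1 keeps per-layer rate variance from collapsing
        # through depth for rate-coded inputs in [0, 1] without biases
        self.net = LayeredNetwork.init_random(
            self.layer_sizes, activation, seed=np.random.default_rng(seed)
        )
        for l in range(len(self.net.W)):
            self.net.W[l] *= init_gain
        self._q_trained = False

    # -- components -------------------------------------------------------
    def controller(self) -> PIController:
        return _controller(self.k, self.alpha, self.tau_u)

    def pretrain_feedback(self, seed: int | None = None) -> np.ndarray:
        """Anti-Hebbian Q pre-training on the dataset inputs (W frozen).

        The rule fixes the *direction* of Q (its correlation with the
        transposed network Jacobian); the overall scale trades off
        against the controller gain, so the trained Q is rescaled to the
        Frobenius norm of the random initialisation convention,
        sqrt(n_dynamic).
        """
        cfg = self.q_config if seed is None else replace(self.q_config, seed=seed)
        train_feedback_weights(self.net, list(self.dataset.X), cfg, self.controller())
        self.net.Q *= np.sqrt(self.net.n_dynamic) / np.linalg.norm(self.net.Q)
        self._q_trained = True
        return self.net.Q

    def trial(self, x: np.ndarray, y: np.ndarray):
        return run_closed_loop(self.net, x, y, self.controller(), self.duration, self.dt)

    def classification_error(self, dataset: Dataset | None = None) -> float:
        ds = dataset if dataset is not None else self.dataset
        preds = np.array([int(np.argmax(feedforward_pass(self.net, x)[-1])) for x in ds.X])
        return float(np.mean(preds != ds.labels))

    # -- training ---------------------------------------------------------
    def fit(
        self,
        epochs: int = 30,
        shuffle_epoch: int | None = None,
        test_dataset: Dataset | None = None,
        pretrain_q: bool = True,
    ) -> "DeepFeedbackResults":
        """Train; optionally permute the class labels after ``shuffle_epoch``.

        The label shuffle applies a non-identity random permutation of
        the class identities to the whole dataset (the "surprise"
        protocol) and keeps it fixed afterwards.
        """
        if pretrain_q and not self._q_trained:
            self.pretrain_feedback()
        rng = np.random.default_rng(self.seed + 1)
        targets = self.dataset.targets
        labels = self.dataset.labels
        rows = []
        n = len(self.dataset)
        for epoch in range(1, epochs + 1):
            # constant lr while features form, then geometric decay to
            # settle the endpoint; the schedule restarts at a label
            # shuffle (a new task begins there)
            ep0 = epoch - 1
            if shuffle_epoch is not None and epoch > shuffle_epoch:
                ep0 = epoch - 1 - shuffle_epoch
            lr = self.lr * self.lr_decay ** max(0, ep0 - self.lr_hold)
            if shuffle_epoch is not None and epoch == shuffle_epoch + 1:
                # swap labels in random pairs (a random matching): every
                # class identity changes, classes exchange with partners
                n_cls = targets.shape[1]
                order = rng.permutation(n_cls)
                perm = np.arange(n_cls)
                for a, b in zip(order[0::2], order[1::2]):
                    perm[a], perm[b] = b, a
                if n_cls % 2:  # odd leftover joins the last pair as a 3-cycle
                    a, b = order[-1], order[-2]
                    perm[a], perm[b] = perm[b], a
                labels = perm[labels]
                targets = one_hot_targets(labels, n_cls)
            order = rng.permutation(n)
            Ls, Hs, Ts = [], [], []
            for i in order:
                traj = self.trial(self.dataset.X[i], targets[i])
                upd = dh_update_from_trajectory(traj, self.net)
                for l in range(len(self.net.W)):
                    self.net.W[l] += lr * upd.deltas[l]
                Ls.append(mse_loss(traj, targets[i]))
                Hs.append(feedback_cost(traj))
                Ts.append(_censored(time_to_target(traj, self.tol), self.duration))
            row = {
                "epoch": epoch,
                "train_error": self.classification_error(
                    Dataset(self.dataset.X, labels, targets)
                ),
                "mean_L": float(np.mean(Ls)),
                "mean_H": float(np.mean(Hs)),
                "mean_T": float(np.mean(Ts)),
                "shuffled": bool(shuffle_epoch is not None and epoch > shuffle_epoch),
            }
            if test_dataset is not None:
                row["test_error"] = self.classification_error(test_dataset)
            rows.append(row)
        return DeepFeedbackResults(self, self.net, pd.DataFrame(rows), shuffle_epoch)

    # -- update-rule alignment -------------------------------------------
    def update_sets(
        self,
        batch_idx: Sequence[int] | None = None,
        stdp_realizations: int = 0,
        kernel: STDPKernel | None = None,
        seed: int = 0,
    ) -> dict[str, UpdateSet]:
        """Batch-summed updates per rule on identical trajectories.

        Returns DH and delta updates accumulated over the batch's
        closed-loop trajectories, the BP reference on the same samples,
        and (if ``stdp_realizations > 0``) the expected STDP update
        averaged over Poisson conversions of the same trajectories.
        """
        idx = list(batch_idx) if batch_idx is not None else list(range(len(self.dataset)))
        kernel = kernel if kernel is not None else STDPKernel()
        rng = np.random.default_rng(seed)
        acc: dict[str, UpdateSet] = {}

        def add(key: str, upd: UpdateSet) -> None:
            acc[key] = upd if key not in acc else acc[key] + upd

        for i in idx:
            x, y = self.dataset.X[i], self.dataset.targets[i]
            traj = self.trial(x, y)
            add("DH", dh_update_from_trajectory(traj, self.net))
            add("delta", delta_update_from_trajectory(traj, self.net))
            add("BP", bp_update_reference(self.net, x, y))
            if stdp_realizations > 0:
                add("STDP", stdp_expected_update(traj, self.net, kernel, stdp_realizations, rng))
        return acc

    def update_alignment(
        self,
        batch_idx: Sequence[int] | None = None,
        stdp_realizations: int = 0,
        seed: int = 0,
    ) -> pd.DataFrame:
        """R^2 (and slope) of each rule's updates against DH."""
        sets = self.update_sets(batch_idx, stdp_realizations, seed=seed)
        rows = []
        for key, upd in sets.items():
            if key == "DH":
                continue
            slope, r2 = update_regression(sets["DH"], upd)
            rows.append({"pair": f"DH vs {key}", "slope": slope, "r2": r2})
        return pd.DataFrame(rows)


@dataclass
class DeepFeedbackResults:
    model: DeepFeedbackModel
    net: LayeredNetwork
    history: pd.DataFrame
    shuffle_epoch: int | None = None

    def summary(self) -> str:
        h = self.history
        first, last = h.iloc[0], h.iloc[-1]
        lines = [
            "DH-DFC training",
            "=" * 34,
            f"layers                 {self.model.layer_sizes}",
            f"epochs                 {len(h)}",
            f"train error            {first.train_error:.3f} -> {last.train_error:.3f}",
            f"mean L                 {first.mean_L:.4f} -> {last.mean_L:.4f}",
            f"mean H                 {first.mean_H:.4f} -> {last.mean_H:.4f}",
            f"mean T                 {first.mean_T:.3f} -> {last.mean_T:.3f}",
        ]
        if self.shuffle_epoch is not None:
            lines.append(f"label shuffle at epoch {self.shuffle_epoch}")
            lines.append(f"H jump factor          {self.surprise_jump_factor():.2f}")
        return "\n".join(lines)

    # -- surprise diagnostics ---------------------------------------------
    def surprise_jump_factor(self) -> float:
        """mean_H(shuffle+1) / mean_H(shuffle)."""
        if self.shuffle_epoch is None:
            raise ValueError("no shuffle epoch in this run")
        h = self.history.set_index("epoch").mean_H
        return float(h.loc[self.shuffle_epoch + 1] / h.loc[self.shuffle_epoch])

    def surprise_recovery(self) -> tuple[int, int]:
        """(initial_epochs, recovery_epochs) to reach the pre-shuffle H level.

        initial: epochs taken from the start to first reach
        H <= H(shuffle_epoch); recovery: epochs after the shuffle to
        return to that level.
        """
        if self.shuffle_epoch is None:
            raise ValueError("no shuffle epoch in this run")
        h = self.history.set_index("epoch").mean_H
        level = h.loc[self.shuffle_epoch]
        initial = int(next(ep for ep, v in h.items() if v <= level)) - 1
        post = h.loc[self.shuffle_epoch + 1:]
        rec_ep = next((ep for ep, v in post.items() if v <= level), None)
        recovery = (int(rec_ep) - self.shuffle_epoch) if rec_ep is not None else len(h)
        return initial, recovery

    def plot_losses(self):
        import matplotlib.pyplot as plt

        fig, axes = plt.subplots(1, 3, figsize=(11, 3))
        h = self.history
        for ax, col in zip(axes, ("mean_H", "mean_L", "mean_T")):
            ax.plot(h.epoch, h[col])
            ax.set(xlabel="epoch", ylabel=col)
            if self.shuffle_epoch is not None:
                ax.axvline(self.shuffle_epoch, ls="--", c="gray")
        fig.tight_layout()
        return fig


# ===========================================================================
# Predictive coding


class PredictiveCodingModel:
    """Supervised PC classifier trained with Hebbian-error or DH updates."""

    def __init__(
        self,
        dataset: Dataset,
        hidden: Sequence[int] = (16,),
        activation: str = "sigmoid",
        rule: str = "hebbian_error",
        lr: float = 0.2,
        n_steps: int = 30,
        step_size: float = 0.1,
        init_gain: float = 3.0,
        seed: int = 0,
    ) -> None:
        self.dataset = dataset
        self.rule = rule
        self.lr, self.n_steps, self.step_size = lr, n_steps, step_size
        self.seed = seed
        sizes = (dataset.X.shape[1], *hidden, dataset.targets.shape[1])
        self.net = LayeredNetwork.init_random(sizes, activation, seed=np.random.default_rng(seed))
        for l in range(len(self.net.W)):
            self.net.W[l] *= init_gain

    def fit(self, epochs: int = 50) -> "PredictiveCodingResults":
        net, history = train_pc(
            self.net,
            self.dataset,
            rule=self.rule,
            epochs=epochs,
            lr=self.lr,
            n_steps=self.n_steps,
            step_size=self.step_size,
            seed=self.seed,
        )
        return PredictiveCodingResults(self, net, history)


@dataclass
class PredictiveCodingResults:
    model: PredictiveCodingModel
    net: LayeredNetwork
    history: pd.DataFrame

    @property
    def final_accuracy(self) -> float:
        return 1.0 - float(self.history.train_error.iloc[-1])

    def summary(self) -> str:
        h = self.history
        return "\n".join(
            [
                f"Predictive coding ({self.model.rule})",
                "=" * 34,
                f"epochs                 {len(h)}",
                f"train error            {h.train_error.iloc[0]:.3f} -> {h.train_error.iloc[-1]:.3f}",
                f"mean energy            {h.mean_energy.iloc[0]:.4f} -> {h.mean_energy.iloc[-1]:.4f}",
            ]
        )
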