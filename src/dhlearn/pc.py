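"""Supervised predictive coding with Hebbian-error or DH weight updates.

Each layer carries an activity vector x_l and a prediction error
eps_l = x_l - W[l] r(x_{l-1}), where r is the activation phi for hidden
and output layers and the identity for the clamped input layer (inputs
are already firing rates; squashing them again would collapse class
separation).  Inference runs gradient descent on the energy
E = sum_l ||eps_l||^2 / 2 with the input layer clamped to the stimulus
and (in training mode) the output layer clamped to the target:

    x_l <- x_l + eta * (-eps_l + phi'(x_l) o (W[l+1]^T eps_{l+1})).

Error "neurons" are computed quantities (fast-error limit), not
dynamical states.  Training-mode inference records the feedforward
initialisation (output still free) as step 0 and clamps the output from
step 1: the prediction errors act as implicit feedback pulling every
hidden activity toward a state consistent with the target, and the
initial output jump is exactly the activity change that gives the DH
rule its output-layer learning signal.

Weight learning is either the standard Hebbian-error rule
dW[l] = eps_l phi(x_{l-1})^T at the inference fixed point, or the DH
rule integrated along the inference trajectory (DH-PC).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import DivergenceError, LayeredNetwork
from .plasticity import UpdateSet

__all__ = [
    "PCTrajectory",
    "pc_forward",
    "pc_energy",
    "pc_inference",
    "pc_error_update",
    "pc_dh_update",
    "train_pc",
    "pc_predict",
]


@dataclass
class PCTrajectory:
    """Per-layer activities over inference steps.

    ``xs[l]`` has shape (n_states, layer_sizes[l]); layer 0 is the
    clamped input (constant rows).  ``energies[t]`` is the PC energy of
    state t.  ``clamped_output`` marks training mode.
    """

    xs: list[np.ndarray]
    energies: np.ndarray
    clamped_output: bool

    @property
    def n_states(self) -> int:
        return self.xs[0].shape[0]

    def final_state(self) -> list[np.ndarray]:
        return [x[-1] for x in self.xs]


def _pre_rate(net: LayeredNetwork, xs: list[np.ndarray], l: int) -> np.ndarray:
    """Presynaptic rate of layer l: identity for the input, phi above."""
    return xs[l] if l == 0 else net.activation(xs[l])


def pc_forward(net: LayeredNetwork, x: np.ndarray) -> list[np.ndarray]:
    """Zero-energy cascade x_l = W[l] r(x_{l-1}) with x_0 = input."""
    xs = [np.asarray(x, dtype=float)]
    for l, w in enumerate(net.W):
        xs.append(w @ _pre_rate(net, xs, l))
    return xs


def _errors(net: LayeredNetwork, xs: list[np.ndarray]) -> list[np.ndarray]:
    return [xs[l + 1] - net.W[l] @ _pre_rate(net, xs, l) for l in range(len(net.W))]


def pc_energy(net: LayeredNetwork, xs: list[np.ndarray]) -> float:
    return float(sum(0.5 * np.sum(e**2) for e in _errors(net, xs)))


def pc_inference(
    net: LayeredNetwork,
    x: np.ndarray,
    y_target: np.ndarray | None = None,
    n_steps: int = 30,
    step_size: float = 0.1,
    init: str = "feedforward",
) -> PCTrajectory:
    """Gradient-descent inference on the PC energy.

    ``y_target`` given -> training mode (output clamped from step 1);
    ``None`` -> test mode (output free).  ``init`` chooses the starting
    activities: ``"feedforward"`` (the zero-energy cascade) or
    ``"zeros"``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    x = np.asarray(x, dtype=float)
    if init == "feedforward":
        xs = pc_forward(net, x)
    elif init == "zeros":
        xs = [x] + [np.zeros(s) for s in net.layer_sizes[1:]]
    else:
        raise ValueError(f"unknown init {init!r}")
    L = len(net.W)

    states = [[xl.copy() for xl in xs]]
    energies = [pc_energy(net, xs)]

    if y_target is not None:
        y_target = np.asarray(y_target, dtype=float)
        if y_target.shape != (net.n_output,):
            raise ValueError("target shape does not match output layer")
        xs[L] = y_target.copy()

    for _ in range(n_steps):
        eps = _errors(net, xs)
        new = [xs[0]]
        for l in range(1, L + 1):
            if l == L and y_target is not None:
                new.append(xs[L])
                continue
            grad = -eps[l - 1]
            if l < L:
                grad = grad + net.activation(xs[l], derivative=True) * (net.W[l].T @ eps[l])
            new.append(xs[l] + step_size * grad)
        xs = new
        if not all(np.all(np.isfinite(xl)) for xl in xs):
            raise DivergenceError("PC inference diverged; reduce step_size")
        states.append([xl.copy() for xl in xs])
        energies.append(pc_energy(net, xs))

    stacked = [np.stack([s[l] for s in states]) for l in range(L + 1)]
    return PCTrajectory(stacked, np.asarray(energies), y_target is not None)


def pc_error_update(net: LayeredNetwork, xs: list[np.ndarray]) -> UpdateSet:
    """Hebbian-error rule: dW[l] = eps_l r(x_{l-1})^T (descent on E)."""
    eps = _errors(net, xs)
    return UpdateSet(
        [np.outer(eps[l], _pre_rate(net, xs, l)) for l in range(len(net.W))],
        "PC",
    )


def pc_dh_update(pc_traj: PCTrajectory, net: LayeredNetwork) -> UpdateSet:
    """DH rule along the inference trajectory, rates r_l = phi(x_l)."""
    if pc_traj.n_states < 2:
        raise ValueError("need at least two inference states")
    deltas = []
    for l in range(len(net.W)):
        pre = pc_traj.xs[l] if l == 0 else net.activation(pc_traj.xs[l])
        post = net.activation(pc_traj.xs[l + 1])
        dpost = np.diff(post, axis=0)
        deltas.append(dpost.T @ pre[:-1])
    return UpdateSet(deltas, "DH")


def pc_predict(net: LayeredNetwork, X: np.ndarray) -> np.ndarray:
    """Class labels by argmax of the cascade output activity."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    return np.array([int(np.argmax(pc_forward(net, x)[-1])) for x in X])


def train_pc(
    net: LayeredNetwork,
    dataset,
    rule: str = "hebbian_error",
    epochs: int = 50,
    lr: float = 0.2,
    lr_decay: float = 0.9,
    lr_hold: int = 25,
    n_steps: int = 30,
    step_size: float = 0.1,
    seed: int = 0,
) -> tuple[LayeredNetwork, pd.DataFrame]:
    """Per-sample PC inference followed by a weight update.

    ``dataset`` must expose ``X`` (n, d), integer ``labels`` and
    continuous ``targets`` (n, n_out).  The learning rate is held for
    ``lr_hold`` epochs, then decays geometrically to settle the
    endpoint.  Returns the trained network and a per-epoch metrics frame
    (classification error, mean final energy).
    """
    if rule not in ("hebbian_error", "DH"):
        raise ValueError(f"unknown rule {rule!r}")
    rng = np.random.default_rng(seed)
    rows = []
    n = len(dataset.X)
    for epoch in range(1, epochs + 1):
        lr_t = lr * lr_decay ** max(0, epoch - 1 - lr_hold)
        order = rng.permutation(n)
        energies = []
        for i in order:
            traj = pc_inference(net, dataset.X[i], dataset.targets[i], n_steps, step_size)
            if rule == "hebbian_error":
                upd = pc_error_update(net, traj.final_state())
            else:
                upd = pc_dh_update(traj, net)
            for l in range(len(net.W)):
                net.W[l] += lr_t * upd.deltas[l]
            energies.append(traj.energies[-1])
        pred = pc_predict(net, dataset.X)
        err = float(np.mean(pred != dataset.labels))
        rows.append({"epoch": epoch, "train_error": err, "mean_energy": float(np.mean(energies))})
    return net, pd.DataFrame(rows)
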