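"""Feedforward weight-update rules computed from trajectories.

The central rule is the differential Hebbian (DH) update: each synapse
integrates the presynaptic rate times the temporal derivative of the
postsynaptic rate,

    dw  =  sum_t  r_pre(t) * [r_post(t+dt) - r_post(t)].

The forward difference is paired with the presynaptic rate at the
*earlier* step (pre-before-post causality, matching the LTP branch of
the STDP kernel).  When the presynaptic rate is constant the sum
telescopes to the dendritic-error (delta) rule
``r_pre [r_post(T) - r_post(0)]``; with time-varying presynaptic rates
the two differ by a correction that vanishes as learning converges (see
:func:`dh_decomposition`).

A hand-written backprop reference provides the descent direction of the
squared output error for alignment comparisons, and
:func:`update_correlation` measures the coefficient of determination
between two update sets.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import LayeredNetwork, Trajectory, feedforward_pass

__all__ = [
    "UpdateSet",
    "InsufficientDataError",
    "UndefinedCorrelationError",
    "dh_update_from_trajectory",
    "delta_update_from_trajectory",
    "dh_decomposition",
    "bp_update_reference",
    "update_correlation",
    "update_regression",
]


class InsufficientDataError(ValueError):
    """Trajectory too short to form a temporal difference."""


class UndefinedCorrelationError(ValueError):
    """An update set has zero variance; R^2 is undefined."""


@dataclass
class UpdateSet:
    """Per-layer weight-update matrices produced by one plasticity rule."""

    deltas: list[np.ndarray]
    rule: str

    def __post_init__(self) -> None:
        self.deltas = [np.asarray(d, dtype=float) for d in self.deltas]
        for d in self.deltas:
            if not np.all(np.isfinite(d)):
                raise ValueError("update contains non-finite entries")

    def flatten(self) -> np.ndarray:
        return np.concatenate([d.ravel() for d in self.deltas])

    def __add__(self, other: "UpdateSet") -> "UpdateSet":
        return UpdateSet([a + b for a, b in zip(self.deltas, other.deltas)], self.rule)

    def scaled(self, factor: float) -> "UpdateSet":
        return UpdateSet([factor * d for d in self.deltas], self.rule)

    def to_frame(self) -> pd.DataFrame:
        """Flattened long format (layer, row, col, delta) for scatter plots."""
        recs = []
        for l, d in enumerate(self.deltas):
            rows, cols = np.indices(d.shape)
            recs.append(
                pd.DataFrame(
                    {
                        "layer": l,
                        "row": rows.ravel(),
                        "col": cols.ravel(),
                        "delta": d.ravel(),
                    }
                )
            )
        return pd.concat(recs, ignore_index=True)


def _check_traj(traj: Trajectory) -> None:
    if traj.n_steps < 2:
        raise InsufficientDataError("need at least two recorded steps")


def dh_update_from_trajectory(
    traj: Trajectory, net: LayeredNetwork, online: bool = False
) -> UpdateSet:
    """Differential Hebbian update, one matrix per weight layer.

    Proportionality constant is 1; the caller applies the learning rate.
    ``online=True`` accumulates step by step (identical result, provided
    for the streaming formulation).
    """
    _check_traj(traj)
    deltas = []
    for l in range(len(net.W)):
        pre = traj.layer_rates(l)
        post = traj.layer_rates(l + 1)
        if online:
            acc = np.zeros_like(net.W[l])
            for t in range(traj.n_steps - 1):
                acc += np.outer(post[t + 1] - post[t], pre[t])
            deltas.append(acc)
        else:
            dpost = np.diff(post, axis=0)
            deltas.append(dpost.T @ pre[:-1])
    return UpdateSet(deltas, "DH")


def delta_update_from_trajectory(traj: Trajectory, net: LayeredNetwork) -> UpdateSet:
    """Dendritic-error rule: r_pre(T) [r_post(T) - r_post(0)] per synapse."""
    _check_traj(traj)
    deltas = []
    for l in range(len(net.W)):
        pre = traj.layer_rates(l)
        post = traj.layer_rates(l + 1)
        deltas.append(np.outer(post[-1] - post[0], pre[-1]))
    return UpdateSet(deltas, "delta")


def dh_decomposition(traj: Trajectory, net: LayeredNetwork) -> tuple[UpdateSet, UpdateSet]:
    """Split the DH update into delta-like and presynaptic-drift terms.

    Returns ``(main, correction)`` with
    ``main = r_pre(T) * sum_t dr_post(t)`` and
    ``correction = sum_t [r_pre(T) - r_pre(t)] dr_post(t)``, so that
    DH = main - correction identically.
    """
    _check_traj(traj)
    mains, corrs = [], []
    for l in range(len(net.W)):
        pre = traj.layer_rates(l)
        post = traj.layer_rates(l + 1)
        dpost = np.diff(post, axis=0)
        main = np.outer(dpost.sum(axis=0), pre[-1])
        corr = dpost.T @ (pre[-1][None, :] - pre[:-1])
        mains.append(main)
        corrs.append(corr)
    return UpdateSet(mains, "DH-main"), UpdateSet(corrs, "DH-correction")


def bp_update_reference(
    net: LayeredNetwork, x: np.ndarray, y_target: np.ndarray
) -> UpdateSet:
    """Exact negative gradient of 0.5 ||y - r_out||^2 on the open-loop pass."""
    y_target = np.asarray(y_target, dtype=float)
    if y_target.shape != (net.n_output,):
        raise ValueError(f"target has shape {y_target.shape}, expected ({net.n_output},)")
    rates = feedforward_pass(net, x)
    pots = [net.W[l] @ rates[l] for l in range(len(net.W))]
    # delta_l = dL/dv_l, negated into a descent direction at the end
    L = len(net.W)
    deltas_v: list[np.ndarray] = [None] * L
    err = y_target - rates[-1]
    deltas_v[L - 1] = err * net.activation(pots[-1], derivative=True)
    for l in range(L - 2, -1, -1):
        back = net.W[l + 1].T @ deltas_v[l + 1]
        deltas_v[l] = back * net.activation(pots[l], derivative=True)
    grads = [np.outer(deltas_v[l], rates[l]) for l in range(L)]
    return UpdateSet(grads, "BP")


def _flat_pair(a: UpdateSet, b: UpdateSet) -> tuple[np.ndarray, np.ndarray]:
    fa, fb = a.flatten(), b.flatten()
    if fa.shape != fb.shape:
        raise ValueError("update sets have mismatched shapes")
    if np.std(fa) == 0 or np.std(fb) == 0:
        raise UndefinedCorrelationError("zero-variance update set")
    return fa, fb


def update_regression(a: UpdateSet, b: UpdateSet) -> tuple[float, float]:
    """Least-squares fit of b's entries on a's: returns (slope, R^2)."""
    fa, fb = _flat_pair(a, b)
    res = stats.linregress(fa, fb)
    return float(res.slope), float(res.rvalue**2)


def update_correlation(a: UpdateSet, b: UpdateSet) -> float:
    """Coefficient of determination of the linear fit of b against a."""
    return update_regression(a, b)[1]
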