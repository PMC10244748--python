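"""The three equivalent training losses: MSE L, feedback cost H, latency T.

L is measured at stimulus onset, before feedback acts (trials start at
the open-loop equilibrium, so this is the error the feedforward pathway
makes on its own).  H integrates the (squared) controller signal over
the trial — the amount of top-down feedback spent.  T is the first time
the output error falls and *stays* within tolerance; never reaching it
returns +inf, and epoch-level aggregation censors that at the trial
duration.
"""

from __future__ import annotations

import numpy as np

from .network import Trajectory

__all__ = ["mse_loss", "feedback_cost", "time_to_target", "NOT_REACHED"]

NOT_REACHED = np.inf
"""Sentinel returned by :func:`time_to_target` when tolerance is never held."""


def mse_loss(traj: Trajectory, y_target: np.ndarray) -> float:
    """Mean squared output error at the pre-feedback initial step."""
    y_target = np.asarray(y_target, dtype=float)
    r0 = traj.output_rates[0]
    if y_target.shape != r0.shape:
        raise ValueError("target shape does not match output layer")
    return float(np.mean((y_target - r0) ** 2))


def feedback_cost(traj: Trajectory, squared: bool = True) -> float:
    """Integral of the controller-signal norm over the trial.

    Default is the squared-norm integral (the control-cost convention);
    ``squared=False`` integrates the plain norm instead.
    """
    dt = traj.dt
    norms = np.sum(traj.c**2, axis=1)
    if not squared:
        norms = np.sqrt(norms)
    # left Riemann sum over the applied-control steps
    return float(np.sum(norms[:-1]) * dt) if traj.n_steps > 1 else 0.0


def time_to_target(traj: Trajectory, tol: float = 0.1) -> float:
    """First time the max-norm output error is sustainedly below tol.

    "Sustained" means the error stays below tol for the remainder of the
    trial, which ignores transient crossings.  Returns seconds from
    trial onset, or :data:`NOT_REACHED` (+inf).
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    err = np.max(np.abs(traj.e), axis=1)
    below = err < tol
    # suffix-AND: ok[t] True iff below from t to the end
    ok = np.logical_and.accumulate(below[::-1])[::-1]
    idx = np.argmax(ok)
    if not ok[idx]:
        return NOT_REACHED
    return float(traj.times[idx] - traj.times[0])
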