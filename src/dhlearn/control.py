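"""Global PI feedback controller and anti-Hebbian feedback-weight learning.

A single proportional-integral controller watches the output error
``e(t) = y_target - r_out(t)`` and emits

    c(t) = c_int(t) + k e(t),      tau_u dc_int/dt = e(t)/alpha - c_int(t),

which is broadcast into every hidden and output neuron through the
feedback matrix ``Q``.  Note the leaky integral: at a constant error the
integral term settles at ``e/alpha``, so the closed-loop gain is
``k + 1/alpha`` rather than infinite.  The default ``alpha = 0.1`` puts
the loop in the strong-feedback regime this framework assumes; with a
weak loop the controlled output never comes close enough to the target
for latency-style losses to be meaningful.

``Q`` itself is learned before feedforward training by injecting white
noise into every neuron while the controller tracks the noise-free
output, with the anti-Hebbian rule  dQ/dt = -v c^T - beta Q.  The
noise-driven correlation aligns Q with the transpose of the network
Jacobian, after which it is frozen.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .network import (
    DivergenceError,
    LayeredNetwork,
    Trajectory,
    feedforward_pass,
    integrate_dynamics,
    open_loop_potentials,
)

__all__ = [
    "PIController",
    "controller_step",
    "ControlInstabilityError",
    "FeedbackTrainingConfig",
    "run_closed_loop",
    "train_feedback_weights",
]

_V_DIVERGE = 1e6


class ControlInstabilityError(DivergenceError):
    """Closed loop diverged; try a smaller gain k, alpha^-1, or dt."""


@dataclass
class PIController:
    """PI controller state and constants.

    k : proportional gain (>= 0)
    alpha : integral leak constant (> 0); steady-state c_int = e/alpha
    tau_u : integral time constant (> 0)
    c_int : current integral term (output dimension)
    """

    k: float = 0.5
    alpha: float = 0.1
    tau_u: float = 1.0
    c_int: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.k < 0 or self.alpha <= 0 or self.tau_u <= 0:
            raise ValueError("require k >= 0, alpha > 0, tau_u > 0")
        if self.c_int is not None:
            self.c_int = np.asarray(self.c_int, dtype=float)

    def reset(self, n_out: int) -> None:
        """Zero the integral term at stimulus onset (independent trials)."""
        self.c_int = np.zeros(n_out)

    def step(self, e: np.ndarray, dt: float) -> np.ndarray:
        """One Euler step; returns c computed from the pre-update c_int."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        e = np.asarray(e, dtype=float)
        if not np.all(np.isfinite(e)):
            raise DivergenceError("non-finite output error fed to controller")
        if self.c_int is None:
            self.reset(e.shape[0])
        c = self.c_int + self.k * e
        self.c_int = self.c_int + (dt / self.tau_u) * (e / self.alpha - self.c_int)
        return c


def controller_step(state: PIController, e: np.ndarray, dt: float) -> tuple[np.ndarray, PIController]:
    """Functional wrapper around :meth:`PIController.step`."""
    c = state.step(e, dt)
    return c, state


def run_closed_loop(
    net: LayeredNetwork,
    x: np.ndarray,
    y_target: np.ndarray,
    controller: PIController | None = None,
    duration: float = 2.0,
    dt: float = 0.02,
    noise_sd: float = 0.0,
    seed: int | np.random.Generator | None = None,
    start_at_equilibrium: bool = True,
) -> Trajectory:
    """Simulate network + PI controller tracking ``y_target``.

    The trial starts from the open-loop equilibrium for the clamped
    stimulus (the network has settled before feedback engages), so the
    error at the first recorded step is the pre-feedback error.  The
    integral term is reset at onset.
    """
    y_target = np.asarray(y_target, dtype=float)
    if y_target.shape != (net.n_output,):
        raise ValueError(f"target has shape {y_target.shape}, expected ({net.n_output},)")
    ctrl = controller if controller is not None else PIController()
    ctrl.reset(net.n_output)

    e_log: list[np.ndarray] = []

    def feedback(t: float, v: np.ndarray, r_full: np.ndarray) -> np.ndarray:
        if np.max(np.abs(v)) > _V_DIVERGE:
            raise ControlInstabilityError(
                "closed-loop potentials exceeded 1e6; reduce k, 1/alpha, or dt"
            )
        e = y_target - r_full[-net.n_output:]
        e_log.append(e)
        return ctrl.step(e, dt)

    traj = integrate_dynamics(
        net,
        x,
        feedback_source=feedback,
        noise_sd=noise_sd,
        duration=duration,
        dt=dt,
        seed=seed,
        v0="equilibrium" if start_at_equilibrium else None,
    )
    traj.e = np.asarray(e_log)
    return traj


@dataclass
class FeedbackTrainingConfig:
    """Constants for noise-driven anti-Hebbian learning of Q.

    beta : weight decay of the anti-Hebbian rule (> 0), bounds ||Q||.
    noise_sd : std of the white noise injected into every potential.
    lr_q : learning-step scale multiplying dt.
    n_episodes : number of stimulus presentations.
    duration, dt : length and step of each presentation.
    seed : RNG seed for the injected noise.
    subtract_baseline : correlate the controller signal with the
        *fluctuation* of the potential around its noise-free equilibrium
        rather than the raw potential.  The fluctuation is what carries
        the credit information; with the raw potential the constant
        baseline swamps the correlation.  Disable for the literal
        raw-potential rule.
    """

    beta: float = 0.01
    noise_sd: float = 1.0
    lr_q: float = 1.0
    n_episodes: int = 200
    subtract_baseline: bool = True
    duration: float = 2.0
    dt: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.beta, self.noise_sd, self.lr_q, self.duration, self.dt) <= 0 or self.n_episodes <= 0:
            raise ValueError("all feedback-training constants must be positive")


def train_feedback_weights(
    net: LayeredNetwork,
    inputs: Sequence[np.ndarray] | np.ndarray,
    cfg: FeedbackTrainingConfig | None = None,
    controller: PIController | None = None,
) -> np.ndarray:
    """Pre-train Q with the anti-Hebbian rule under injected noise.

    For each presentation the target is the *noise-free* open-loop
    output, so the controller only fights the injected fluctuations; the
    per-step update  Q += lr_q dt (-v c^T - beta Q)  then correlates each
    neuron's fluctuation with the corrective signal.  ``net.Q`` is
    updated in place and returned.  Feedforward weights stay frozen.
    """
    cfg = cfg if cfg is not None else FeedbackTrainingConfig()
    ctrl = controller if controller is not None else PIController()
    inputs = [np.asarray(x, dtype=float) for x in inputs]
    if not inputs:
        raise ValueError("need at least one input sample")
    rng = np.random.default_rng(cfg.seed)
    n_steps = int(round(cfg.duration / cfg.dt))
    dt = cfg.dt

    for ep in range(cfg.n_episodes):
        x = inputs[ep % len(inputs)]
        y = feedforward_pass(net, x)[-1]
        ctrl.reset(net.n_output)
        v = open_loop_potentials(net, x)
        v_baseline = v.copy() if cfg.subtract_baseline else 0.0
        for _ in range(n_steps):
            r_full = net.rates_from_state(x, v)
            e = y - r_full[-net.n_output:]
            c = ctrl.step(e, dt)
            dv = -v + net.drive(r_full) + net.Q @ c + rng.normal(0.0, cfg.noise_sd, net.n_dynamic)
            dq = -np.outer(v - v_baseline, c) - cfg.beta * net.Q
            v = v + dt * dv
            net.Q += cfg.lr_q * dt * dq
            if not np.all(np.isfinite(v)) or np.max(np.abs(v)) > _V_DIVERGE:
                raise ControlInstabilityError("feedback-weight training diverged")
    if not np.all(np.isfinite(net.Q)):
        raise ControlInstabilityError("Q became non-finite during training")
    return net.Q
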