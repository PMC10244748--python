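"""Leaky rate-network dynamics.

A :class:`LayeredNetwork` is a feedforward stack of rate neurons.  Every
non-input neuron integrates a leaky membrane potential

    dv/dt = -v + W r_pre + Q c (+ noise),      r = phi(v),

with the membrane time constant fixed to 1 (time is measured in units of
it) and the input layer clamped to the stimulus rates.  ``c`` is an
apical feedback signal of output dimension, broadcast to every
hidden/output neuron through the feedback matrix ``Q``; in open-loop
simulations ``c = 0``.

The module provides the open-loop cascade fixed point
(:func:`feedforward_pass`), forward-Euler integration of the dynamics
(:func:`integrate_dynamics`), and the :class:`Trajectory` record that the
plasticity rules consume.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ActivationFunction",
    "LayeredNetwork",
    "Trajectory",
    "ConfigurationError",
    "DivergenceError",
    "feedforward_pass",
    "open_loop_potentials",
    "integrate_dynamics",
    "activation_apply",
]


class ConfigurationError(ValueError):
    """Raised for unknown activation names or inconsistent shapes."""


class DivergenceError(RuntimeError):
    """Raised when the integrated state becomes non-finite or unbounded."""


def _sigmoid(v: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(v, dtype=float)
    pos = v >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-v[pos]))
    ev = np.exp(v[~pos])
    out[~pos] = ev / (1.0 + ev)
    return out


def _sigmoid_prime(v: np.ndarray) -> np.ndarray:
    s = _sigmoid(v)
    return s * (1.0 - s)


_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "sigmoid": (_sigmoid, _sigmoid_prime),
    "tanh": (np.tanh, lambda v: 1.0 - np.tanh(v) ** 2),
    "linear": (lambda v: np.asarray(v, dtype=float), lambda v: np.ones_like(np.asarray(v, dtype=float))),
}


@dataclass(frozen=True)
class ActivationFunction:
    """Pointwise rate function phi with its derivative.

    ``linear`` is provided for tests and analysis; the biological model
    uses the bounded ``sigmoid`` (rates are then per-bin spike
    probabilities in [0, 1]).
    """

    name: str

    def __post_init__(self) -> None:
        if self.name not in _ACTIVATIONS:
            raise ConfigurationError(
                f"unknown activation {self.name!r}; choose from {sorted(_ACTIVATIONS)}"
            )

    def __call__(self, v: np.ndarray, derivative: bool = False) -> np.ndarray:
        f, df = _ACTIVATIONS[self.name]
        v = np.asarray(v, dtype=float)
        return df(v) if derivative else f(v)


def activation_apply(act: ActivationFunction | str, v: np.ndarray, derivative: bool = False) -> np.ndarray:
    """Apply phi (or phi') elementwise."""
    if isinstance(act, str):
        act = ActivationFunction(act)
    v = np.asarray(v, dtype=float)
    if not np.all(np.isfinite(v)):
        raise ValueError("non-finite potential passed to activation")
    return act(v, derivative=derivative)


@dataclass
class LayeredNetwork:
    """Feedforward rate network with a global feedback matrix.

    Parameters
    ----------
    layer_sizes : sizes (input, hidden..., output).
    W : list of weight matrices; ``W[l]`` maps layer ``l`` rates to layer
        ``l+1`` potentials, shape ``(layer_sizes[l+1], layer_sizes[l])``.
    Q : feedback matrix mapping the controller signal (output dimension)
        into every non-input neuron, shape ``(n_dynamic, n_output)``.
    activation : shared rate function.
    """

    layer_sizes: tuple[int, ...]
    W: list[np.ndarray]
    Q: np.ndarray
    activation: ActivationFunction = field(default_factory=lambda: ActivationFunction("sigmoid"))

    def __post_init__(self) -> None:
        self.layer_sizes = tuple(int(s) for s in self.layer_sizes)
        if len(self.layer_sizes) < 2 or any(s <= 0 for s in self.layer_sizes):
            raise ConfigurationError("layer_sizes must be >= 2 positive integers")
        if isinstance(self.activation, str):
            self.activation = ActivationFunction(self.activation)
        self.W = [np.array(w, dtype=float) for w in self.W]
        if len(self.W) != len(self.layer_sizes) - 1:
            raise ConfigurationError("need one weight matrix per layer transition")
        for l, w in enumerate(self.W):
            expect = (self.layer_sizes[l + 1], self.layer_sizes[l])
            if w.shape != expect:
                raise ConfigurationError(f"W[{l}] has shape {w.shape}, expected {expect}")
            if not np.all(np.isfinite(w)):
                raise ConfigurationError(f"W[{l}] contains non-finite entries")
        self.Q = np.array(self.Q, dtype=float)
        if self.Q.shape != (self.n_dynamic, self.n_output):
            raise ConfigurationError(
                f"Q has shape {self.Q.shape}, expected {(self.n_dynamic, self.n_output)}"
            )
        if not np.all(np.isfinite(self.Q)):
            raise ConfigurationError("Q contains non-finite entries")

    # -- geometry helpers -------------------------------------------------
    @property
    def n_input(self) -> int:
        return self.layer_sizes[0]

    @property
    def n_output(self) -> int:
        return self.layer_sizes[-1]

    @property
    def n_dynamic(self) -> int:
        """Number of neurons obeying the leaky dynamics (hidden + output)."""
        return sum(self.layer_sizes[1:])

    @property
    def n_total(self) -> int:
        return sum(self.layer_sizes)

    def dynamic_slices(self) -> list[slice]:
        """Slices of each non-input layer within the concatenated state."""
        out, start = [], 0
        for s in self.layer_sizes[1:]:
            out.append(slice(start, start + s))
            start += s
        return out

    def rate_slices(self) -> list[slice]:
        """Slices of every layer (input included) within the full rate vector."""
        out, start = [], 0
        for s in self.layer_sizes:
            out.append(slice(start, start + s))
            start += s
        return out

    def copy(self) -> "LayeredNetwork":
        return LayeredNetwork(
            self.layer_sizes,
            [w.copy() for w in self.W],
            self.Q.copy(),
            self.activation,
        )

    @classmethod
    def init_random(
        cls,
        layer_sizes: Sequence[int],
        activation: str | ActivationFunction = "sigmoid",
        seed: int | np.random.Generator | None = 0,
        w_scale: float | None = None,
        q_scale: float | None = None,
    ) -> "LayeredNetwork":
        """Gaussian initialisation, std 1/sqrt(fan_in) unless overridden."""
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        layer_sizes = tuple(int(s) for s in layer_sizes)
        W = []
        for l in range(len(layer_sizes) - 1):
            scale = w_scale if w_scale is not None else 1.0 / np.sqrt(layer_sizes[l])
            W.append(rng.normal(0.0, scale, size=(layer_sizes[l + 1], layer_sizes[l])))
        n_dyn, n_out = sum(layer_sizes[1:]), layer_sizes[-1]
        qs = q_scale if q_scale is not None else 1.0 / np.sqrt(n_out)
        Q = rng.normal(0.0, qs, size=(n_dyn, n_out))
        return cls(layer_sizes, W, Q, ActivationFunction(activation) if isinstance(activation, str) else activation)

    # -- dynamics helpers --------------------------------------------------
    def drive(self, rates_full: np.ndarray) -> np.ndarray:
        """Feedforward drive W r_pre for every non-input neuron."""
        rs = self.rate_slices()
        return np.concatenate(
            [self.W[l] @ rates_full[rs[l]] for l in range(len(self.W))]
        )

    def rates_from_state(self, x: np.ndarray, v: np.ndarray) -> np.ndarray:
        """Full rate vector: clamped input rates followed by phi(v)."""
        return np.concatenate([np.asarray(x, dtype=float), self.activation(v)])


@dataclass
class Trajectory:
    """Time-indexed record of one stimulus presentation.

    Arrays share the time axis: ``times`` (T,), potentials ``v``
    (T, n_dynamic), full rates ``r`` (T, n_total, input layer included and
    clamped), controller signal ``c`` (T, n_output) and output error ``e``
    (T, n_output); open-loop runs carry zeros in ``c`` and ``e``.
    """

    times: np.ndarray
    v: np.ndarray
    r: np.ndarray
    c: np.ndarray
    e: np.ndarray
    layer_sizes: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.times)
        for name in ("v", "r", "c", "e"):
            arr = getattr(self, name)
            if arr.shape[0] != n:
                raise ValueError(f"{name} does not share the time axis (length {n})")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0]) if len(self.times) > 1 else 0.0

    @property
    def n_steps(self) -> int:
        return len(self.times)

    def _rate_offsets(self) -> list[slice]:
        out, start = [], 0
        for s in self.layer_sizes:
            out.append(slice(start, start + s))
            start += s
        return out

    def layer_rates(self, layer: int) -> np.ndarray:
        """Rates of one layer over time, layer 0 = input."""
        return self.r[:, self._rate_offsets()[layer]]

    @property
    def output_rates(self) -> np.ndarray:
        return self.layer_rates(len(self.layer_sizes) - 1)

    def to_frame(self) -> pd.DataFrame:
        cols: dict[str, np.ndarray] = {"t": self.times}
        for i in range(self.v.shape[1]):
            cols[f"v{i}"] = self.v[:, i]
        for i in range(self.r.shape[1]):
            cols[f"r{i}"] = self.r[:, i]
        for i in range(self.c.shape[1]):
            cols[f"c{i}"] = self.c[:, i]
        for i in range(self.e.shape[1]):
            cols[f"e{i}"] = self.e[:, i]
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def feedforward_pass(net: LayeredNetwork, x: np.ndarray) -> list[np.ndarray]:
    """Open-loop cascade fixed point: per-layer rates with c = 0.

    With the input clamped, the equilibrium of the leaky dynamics is
    reached layer by layer: v_l = W[l-1] r_{l-1}, r_l = phi(v_l).
    """
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_input,):
        raise ConfigurationError(f"input has shape {x.shape}, expected ({net.n_input},)")
    rates = [x]
    for w in net.W:
        rates.append(net.activation(w @ rates[-1]))
    return rates


def open_loop_potentials(net: LayeredNetwork, x: np.ndarray) -> np.ndarray:
    """Equilibrium membrane potentials of the open-loop cascade."""
    rates = feedforward_pass(net, x)
    return np.concatenate([net.W[l] @ rates[l] for l in range(len(net.W))])


def integrate_dynamics(
    net: LayeredNetwork,
    x: np.ndarray,
    feedback_source: Callable[[float, np.ndarray, np.ndarray], np.ndarray] | None = None,
    noise_sd: float = 0.0,
    duration: float = 10.0,
    dt: float = 0.01,
    seed: int | np.random.Generator | None = None,
    v0: np.ndarray | str | None = None,
) -> Trajectory:
    """Forward-Euler integration of the leaky rate dynamics.

    Parameters
    ----------
    feedback_source : callable ``f(t, v, r_full) -> c`` returning the
        controller signal (output dimension); ``None`` means open loop.
        It is evaluated once per step (and once at the final state so the
        record covers every sample).
    noise_sd : standard deviation of the zero-mean Gaussian noise added
        inside the potential update, fresh per step and neuron.
    v0 : initial potentials; ``None`` -> zeros, ``"equilibrium"`` -> the
        open-loop cascade fixed point for ``x``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    if duration < dt:
        raise ValueError("duration must be at least one step")
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    x = np.asarray(x, dtype=float)
    if x.shape != (net.n_input,):
        raise ConfigurationError(f"input has shape {x.shape}, expected ({net.n_input},)")

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_steps = int(round(duration / dt))
    n_rec = n_steps + 1

    if isinstance(v0, str):
        if v0 != "equilibrium":
            raise ConfigurationError(f"unknown v0 mode {v0!r}")
        v = open_loop_potentials(net, x)
    elif v0 is None:
        v = np.zeros(net.n_dynamic)
    else:
        v = np.array(v0, dtype=float)
        if v.shape != (net.n_dynamic,):
            raise ConfigurationError("v0 has wrong shape")

    times = np.arange(n_rec) * dt
    V = np.empty((n_rec, net.n_dynamic))
    R = np.empty((n_rec, net.n_total))
    C = np.zeros((n_rec, net.n_output))

    for step in range(n_rec):
        r_full = net.rates_from_state(x, v)
        V[step] = v
        R[step] = r_full
        if feedback_source is not None:
            c = np.asarray(feedback_source(times[step], v, r_full), dtype=float)
            C[step] = c
        else:
            c = None
        if step == n_steps:
            break
        dv = -v + net.drive(r_full)
        if c is not None:
            dv = dv + net.Q @ c
        if noise_sd > 0:
            dv = dv + rng.normal(0.0, noise_sd, size=net.n_dynamic)
        v = v + dt * dv
        if not np.all(np.isfinite(v)):
            raise DivergenceError(f"state became non-finite at step {step + 1}")

    return Trajectory(times, V, R, C, np.zeros_like(C), net.layer_sizes)
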