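"""Rate-to-spike conversion and pairwise-kernel STDP updates.

Rates are interpreted as per-bin spike probabilities (an inhomogeneous
Poisson/Bernoulli process on the integration grid), so the trajectory
step ``dt`` sets the rate scale.  The STDP update sums an exponential
kernel over spike pairs: a presynaptic spike preceding a postsynaptic
one potentiates (+a_plus e^{-dt/tau_plus}), the reverse order depresses.

The default kernel is *balanced* (a_plus tau_plus = a_minus tau_minus).
Under independent Poisson sampling the expected pair-based update
decomposes into a term proportional to the rate product (weighted by the
kernel imbalance) plus a term tracking the postsynaptic rate derivative;
a balanced kernel cancels the first, so the expectation follows the
differential Hebbian signal — the correspondence this package is about.
The biologically skewed profile (larger LTD) remains available through
the kernel parameters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import LayeredNetwork, Trajectory
from .plasticity import UpdateSet

__all__ = [
    "STDPKernel",
    "SpikeTrainSet",
    "rates_to_poisson_spikes",
    "stdp_pairwise_update",
    "stdp_expected_update",
]


@dataclass(frozen=True)
class STDPKernel:
    """Exponential pair-based STDP kernel.

    Amplitudes are dimensionless weight increments; time constants are in
    trajectory time units (1 unit = 1 membrane time constant; the default
    0.02 corresponds to the classical ~20 ms window when a unit is read
    as one second).  ``window_mult`` truncates the pair sum at
    ``window_mult * tau`` (error < e^-5 per pair at the default).
    """

    a_plus: float = 0.01
    a_minus: float = 0.01
    tau_plus: float = 0.02
    tau_minus: float = 0.02
    pairing: str = "all_to_all"
    window_mult: float = 5.0

    def __post_init__(self) -> None:
        if self.a_plus < 0 or self.a_minus < 0:
            raise ValueError("amplitudes must be non-negative")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("time constants must be positive")
        if self.pairing not in ("all_to_all", "nearest_neighbor"):
            raise ValueError(f"unknown pairing {self.pairing!r}")


@dataclass
class SpikeTrainSet:
    """Per-neuron ordered spike times produced from a rate trajectory."""

    trains: list[np.ndarray]
    duration: float
    dt: float

    def __post_init__(self) -> None:
        for i, tr in enumerate(self.trains):
            tr = np.asarray(tr, dtype=float)
            if tr.size and (np.any(np.diff(tr) <= 0) or tr[0] < 0 or tr[-1] > self.duration):
                raise ValueError(f"train {i} is not strictly increasing within [0, duration]")
            self.trains[i] = tr

    def __len__(self) -> int:
        return len(self.trains)


def rates_to_poisson_spikes(
    traj: Trajectory,
    seed: int | np.random.Generator | None = None,
) -> SpikeTrainSet:
    """Bernoulli spike conversion: P(spike in bin t) = r(t), per neuron.

    All neurons in the trajectory (input layer included) are converted;
    rates must be valid probabilities.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = traj.r
    bad = (r < 0) | (r > 1)
    if np.any(bad):
        t_idx, n_idx = np.argwhere(bad)[0]
        raise ValueError(
            f"rate {r[t_idx, n_idx]:.4g} outside [0, 1] at neuron {n_idx}, step {t_idx}"
        )
    spikes = rng.random(r.shape) < r
    trains = [traj.times[spikes[:, i]] for i in range(r.shape[1])]
    return SpikeTrainSet(trains, float(traj.times[-1]), traj.dt)


def _spike_matrix(traj: Trajectory, rng: np.random.Generator) -> np.ndarray:
    """Boolean (T, n_neurons) spike raster; validity checked by caller."""
    return rng.random(traj.r.shape) < traj.r


def stdp_pairwise_update(
    pre: np.ndarray, post: np.ndarray, kernel: STDPKernel = STDPKernel()
) -> float:
    """Sum the pair kernel over a pre/post spike-time pair of trains.

    ``all_to_all`` superposes every pair within the truncation window;
    ``nearest_neighbor`` pairs each spike only with the closest earlier
    spike of the other train.  Simultaneous spikes contribute nothing.
    """
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    for name, tr in (("pre", pre), ("post", post)):
        if tr.size > 1 and np.any(np.diff(tr) <= 0):
            raise ValueError(f"{name} train must be strictly increasing")
    if pre.size == 0 or post.size == 0:
        return 0.0

    if kernel.pairing == "all_to_all":
        diffs = post[None, :] - pre[:, None]  # t_post - t_pre
        ltp = (diffs > 0) & (diffs <= kernel.window_mult * kernel.tau_plus)
        ltd = (diffs < 0) & (-diffs <= kernel.window_mult * kernel.tau_minus)
        dw = kernel.a_plus * np.exp(-diffs[ltp] / kernel.tau_plus).sum()
        dw -= kernel.a_minus * np.exp(diffs[ltd] / kernel.tau_minus).sum()
        return float(dw)

    # nearest neighbour: latest pre before each post (LTP), latest post
    # before each pre (LTD)
    dw = 0.0
    idx = np.searchsorted(pre, post, side="left") - 1
    for j, i in enumerate(idx):
        if i >= 0:
            d = post[j] - pre[i]
            if 0 < d <= kernel.window_mult * kernel.tau_plus:
                dw += kernel.a_plus * np.exp(-d / kernel.tau_plus)
    idx = np.searchsorted(post, pre, side="left") - 1
    for j, i in enumerate(idx):
        if i >= 0:
            d = pre[j] - post[i]
            if 0 < d <= kernel.window_mult * kernel.tau_minus:
                dw -= kernel.a_minus * np.exp(-d / kernel.tau_minus)
    return float(dw)


def _stdp_matrix_all_to_all(
    spikes: np.ndarray,
    pre_cols: slice,
    post_cols: slice,
    dt: float,
    kernel: STDPKernel,
) -> np.ndarray:
    """Exact all-to-all pair sum via exponential traces on the grid.

    For grid-aligned spikes the double sum over pairs equals a single
    pass with low-pass filtered spike counts, with no window truncation:
    dW[i, j] = a+ sum_t s_post(t, i) P_pre(t, j) - a- sum_t s_pre(t, j) P_post(t, i),
    where P is the trace of earlier spikes decayed by exp(-s dt / tau).
    """
    s_pre = spikes[:, pre_cols].astype(float)
    s_post = spikes[:, post_cols].astype(float)
    T = spikes.shape[0]
    decay_p = np.exp(-dt / kernel.tau_plus)
    decay_m = np.exp(-dt / kernel.tau_minus)
    tr_pre = np.zeros(s_pre.shape[1])
    tr_post = np.zeros(s_post.shape[1])
    ltp = np.zeros((s_post.shape[1], s_pre.shape[1]))
    ltd = np.zeros((s_post.shape[1], s_pre.shape[1]))
    for t in range(T):
        # traces hold spikes strictly earlier than t -> same-bin pairs excluded
        ltp += np.outer(s_post[t], tr_pre)
        ltd += np.outer(tr_post, s_pre[t])
        tr_pre = (tr_pre + s_pre[t]) * decay_p
        tr_post = (tr_post + s_post[t]) * decay_m
    return kernel.a_plus * ltp - kernel.a_minus * ltd


def stdp_expected_update(
    traj: Trajectory,
    net: LayeredNetwork,
    kernel: STDPKernel = STDPKernel(),
    n_realizations: int = 100,
    seed: int | np.random.Generator | None = None,
) -> UpdateSet:
    """Mean STDP update over independent Poisson conversions of ``traj``.

    Averaging parallel realizations beats down the sampling noise of the
    spike conversion so that the pair-based update can be compared with
    its rate-based (DH) expectation.
    """
    if n_realizations < 1:
        raise ValueError("n_realizations must be >= 1")
    r = traj.r
    if np.any((r < 0) | (r > 1)):
        t_idx, n_idx = np.argwhere((r < 0) | (r > 1))[0]
        raise ValueError(
            f"rate {r[t_idx, n_idx]:.4g} outside [0, 1] at neuron {n_idx}, step {t_idx}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    slices = []
    start = 0
    for s in net.layer_sizes:
        slices.append(slice(start, start + s))
        start += s
    acc = [np.zeros_like(w) for w in net.W]
    dt = traj.dt
    for _ in range(n_realizations):
        spikes = _spike_matrix(traj, rng)
        for l in range(len(net.W)):
            if kernel.pairing == "all_to_all":
                acc[l] += _stdp_matrix_all_to_all(spikes, slices[l], slices[l + 1], dt, kernel)
            else:
                times = traj.times
                pre_tr = [times[spikes[:, j]] for j in range(*slices[l].indices(r.shape[1]))]
                post_tr = [times[spikes[:, i]] for i in range(*slices[l + 1].indices(r.shape[1]))]
                for i, ptr in enumerate(post_tr):
                    for j, qtr in enumerate(pre_tr):
                        acc[l][i, j] += stdp_pairwise_update(qtr, ptr, kernel)
    return UpdateSet([a / n_realizations for a in acc], "STDP")
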