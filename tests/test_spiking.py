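"""Poisson spike conversion and pair-based STDP updates."""

import numpy as np
import pytest

from dhlearn.network import LayeredNetwork, Trajectory, integrate_dynamics
from dhlearn.plasticity import dh_update_from_trajectory, update_regression
from dhlearn.spiking import (
    STDPKernel,
    rates_to_poisson_spikes,
    stdp_expected_update,
    stdp_pairwise_update,
)


def flat_rate_traj(rates, n_steps=100, dt=0.01, layer_sizes=(1, 1)):
    """Trajectory with constant per-neuron rates."""
    rates = np.asarray(rates, dtype=float)
    r = np.tile(rates, (n_steps, 1))
    times = np.arange(n_steps) * dt
    n_dyn = sum(layer_sizes[1:])
    z = np.zeros((n_steps, layer_sizes[-1]))
    return Trajectory(times, np.zeros((n_steps, n_dyn)), r, z, z, tuple(layer_sizes))


class TestPoissonConversion:
    def test_zero_rate_gives_empty_trains(self):
        traj = flat_rate_traj([0.0, 0.0])
        st = rates_to_poisson_spikes(traj, seed=0)
        assert all(len(t) == 0 for t in st.trains)

    def test_unit_rate_spikes_every_bin(self):
        traj = flat_rate_traj([1.0, 1.0], n_steps=50)
        st = rates_to_poisson_spikes(traj, seed=0)
        assert all(len(t) == 50 for t in st.trains)

    def test_half_rate_count_is_binomial(self):
        traj = flat_rate_traj([0.5, 0.5], n_steps=10_000)
        st = rates_to_poisson_spikes(traj, seed=1)
        for t in st.trains:
            assert abs(len(t) - 5000) < 3 * np.sqrt(10_000 * 0.25)

    def test_out_of_range_rate_names_neuron_and_step(self):
        traj = flat_rate_traj([0.5, 0.5])
        traj.r[7, 1] = 1.3
        with pytest.raises(ValueError, match="neuron 1.*step 7"):
            rates_to_poisson_spikes(traj, seed=0)

    def test_seeded_determinism(self):
        traj = flat_rate_traj([0.3, 0.6])
        a = rates_to_poisson_spikes(traj, seed=9)
        b = rates_to_poisson_spikes(traj, seed=9)
        assert all(np.array_equal(x, y) for x, y in zip(a.trains, b.trains))


class TestPairwiseKernel:
    def test_empty_train_gives_zero(self):
        k = STDPKernel()
        assert stdp_pairwise_update(np.array([]), np.array([0.01, 0.02]), k) == 0.0
        assert stdp_pairwise_update(np.array([0.01]), np.array([]), k) == 0.0

    def test_single_ltp_pair(self):
        """pre at 10 ms before post: a_plus * exp(-dt/tau_plus)."""
        k = STDPKernel(a_plus=0.01, tau_plus=0.020)
        dw = stdp_pairwise_update(np.array([0.010]), np.array([0.015]), k)
        assert dw == pytest.approx(0.01 * np.exp(-0.25), rel=1e-9)

    def test_single_ltd_pair(self):
        k = STDPKernel(a_minus=0.012, tau_minus=0.020)
        dw = stdp_pairwise_update(np.array([0.015]), np.array([0.010]), k)
        assert dw == pytest.approx(-0.012 * np.exp(-0.25), rel=1e-9)

    def test_unsorted_train_rejected(self):
        with pytest.raises(ValueError):
            stdp_pairwise_update(np.array([0.02, 0.01]), np.array([0.03]), STDPKernel())

    def test_nearest_neighbor_uses_adjacent_pair_only(self):
        """Two pre spikes before one post: all-to-all counts both, NN one."""
        pre = np.array([0.000, 0.010])
        post = np.array([0.015])
        k_all = STDPKernel(pairing="all_to_all", tau_plus=0.02, tau_minus=0.02)
        k_nn = STDPKernel(pairing="nearest_neighbor", tau_plus=0.02, tau_minus=0.02)
        dw_all = stdp_pairwise_update(pre, post, k_all)
        dw_nn = stdp_pairwise_update(pre, post, k_nn)
        assert dw_nn == pytest.approx(0.01 * np.exp(-0.25), rel=1e-9)
        assert dw_all == pytest.approx(dw_nn + 0.01 * np.exp(-0.75), rel=1e-9)


class TestExpectedUpdate:
    @pytest.fixture
    def tiny_net(self):
        return LayeredNetwork((1, 1), [np.array([[0.3]])], np.ones((1, 1)), "sigmoid")

    def test_trace_method_matches_pairwise_sum(self, tiny_net):
        """The O(T) trace evaluation equals the literal double sum."""
        rng = np.random.default_rng(4)
        r = np.column_stack([rng.uniform(0.2, 0.8, 200), rng.uniform(0.2, 0.8, 200)])
        times = np.arange(200) * 0.01
        z = np.zeros((200, 1))
        traj = Trajectory(times, z.copy(), r, z.copy(), z.copy(), (1, 1))
        kernel = STDPKernel(window_mult=50.0)  # no truncation in the oracle
        upd = stdp_expected_update(traj, tiny_net, kernel, n_realizations=1, seed=11)
        spikes = rates_to_poisson_spikes(traj, seed=np.random.default_rng(11))
        direct = stdp_pairwise_update(spikes.trains[0], spikes.trains[1], kernel)
        assert upd.deltas[0][0, 0] == pytest.approx(direct, rel=1e-9)

    def test_single_realization_reproducible(self, tiny_net):
        traj = flat_rate_traj([0.5, 0.5], n_steps=300)
        a = stdp_expected_update(traj, tiny_net, n_realizations=1, seed=3)
        b = stdp_expected_update(traj, tiny_net, n_realizations=1, seed=3)
        assert a.deltas[0][0, 0] == b.deltas[0][0, 0]

    def test_balanced_kernel_constant_rates_mean_zero(self, tiny_net):
        """Constant rates + balanced kernel: expected update ~ 0 (|mean| < 3 SEM)."""
        traj = flat_rate_traj([0.6, 0.4], n_steps=200)
        n = 500
        vals = []
        rng = np.random.default_rng(0)
        for _ in range(n):
            vals.append(
                stdp_expected_update(traj, tiny_net, n_realizations=1, seed=rng).deltas[0][0, 0]
            )
        vals = np.array(vals)
        sem = vals.std(ddof=1) / np.sqrt(n)
        assert abs(vals.mean()) < 3 * sem

    def test_expected_update_tracks_dh_signal(self, tiny_net):
        """Mean STDP over many conversions regresses on DH with positive slope."""
        # rising postsynaptic rate, constant presynaptic rate
        n_steps = 150
        times = np.arange(n_steps) * 0.01
        post = np.linspace(0.2, 0.8, n_steps)
        r = np.column_stack([np.full(n_steps, 0.7), post])
        z = np.zeros((n_steps, 1))
        traj = Trajectory(times, z.copy(), r, z.copy(), z.copy(), (1, 1))
        upd = stdp_expected_update(traj, tiny_net, n_realizations=800, seed=2)
        dh = dh_update_from_trajectory(traj, tiny_net)
        assert np.sign(upd.deltas[0][0, 0]) == np.sign(dh.deltas[0][0, 0]) == 1.0
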