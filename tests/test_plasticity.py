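"""DH, delta and BP update rules and their algebraic relations."""

import numpy as np
import pytest

from dhlearn.network import LayeredNetwork, Trajectory, feedforward_pass, integrate_dynamics
from dhlearn.plasticity import (
    InsufficientDataError,
    UndefinedCorrelationError,
    UpdateSet,
    bp_update_reference,
    delta_update_from_trajectory,
    dh_decomposition,
    dh_update_from_trajectory,
    update_correlation,
    update_regression,
)


def make_traj(pre, post, net):
    """Trajectory for a 1-1 net from explicit pre/post rate series."""
    pre = np.asarray(pre, dtype=float)
    post = np.asarray(post, dtype=float)
    T = len(pre)
    times = np.arange(T) * 0.1
    r = np.column_stack([pre, post])
    v = post[:, None].copy()
    z = np.zeros((T, 1))
    return Trajectory(times, v, r, z, z, net.layer_sizes)


@pytest.fixture
def unit_net():
    return LayeredNetwork((1, 1), [np.array([[0.2]])], np.ones((1, 1)), "linear")


class TestDHUpdate:
    def test_constant_postsynaptic_rate_gives_zero(self, unit_net):
        traj = make_traj([0.5, 0.7, 0.9], [0.4, 0.4, 0.4], unit_net)
        assert dh_update_from_trajectory(traj, unit_net).deltas[0][0, 0] == 0.0

    def test_constant_pre_telescopes_to_delta_rule(self, unit_net):
        traj = make_traj([1.0, 1.0, 1.0], [0.2, 0.5, 0.9], unit_net)
        dw = dh_update_from_trajectory(traj, unit_net).deltas[0][0, 0]
        assert dw == pytest.approx(0.7, abs=1e-12)
        # and agrees with the explicit delta rule
        dd = delta_update_from_trajectory(traj, unit_net).deltas[0][0, 0]
        assert dw == pytest.approx(dd, abs=1e-12)

    def test_decomposition_identity(self, deep_net):
        """DH = main(delta-like) - presynaptic-drift correction, exactly."""
        traj = integrate_dynamics(
            deep_net, np.array([0.2, 0.8, 0.5]),
            feedback_source=lambda t, v, r: np.array([np.sin(t), np.cos(t)]),
            duration=1.0, dt=0.02,
        )
        dh = dh_update_from_trajectory(traj, deep_net)
        main, corr = dh_decomposition(traj, deep_net)
        for a, m, c in zip(dh.deltas, main.deltas, corr.deltas):
            assert np.allclose(a, m - c, atol=1e-12)

    def test_online_accumulation_equals_batch(self, deep_net):
        traj = integrate_dynamics(deep_net, np.array([0.1, 0.4, 0.9]),
                                  noise_sd=0.3, duration=0.5, dt=0.05, seed=5)
        batch = dh_update_from_trajectory(traj, deep_net)
        online = dh_update_from_trajectory(traj, deep_net, online=True)
        for a, b in zip(batch.deltas, online.deltas):
            assert np.allclose(a, b, atol=1e-14)

    def test_sign_follows_postsynaptic_drift(self, unit_net):
        """Monotone rise of r_post with positive r_pre potentiates; fall depresses."""
        up = make_traj([0.8] * 5, np.linspace(0.2, 0.9, 5), unit_net)
        down = make_traj([0.8] * 5, np.linspace(0.9, 0.2, 5), unit_net)
        assert dh_update_from_trajectory(up, unit_net).deltas[0][0, 0] > 0
        assert dh_update_from_trajectory(down, unit_net).deltas[0][0, 0] < 0

    def test_single_step_trajectory_rejected(self, unit_net):
        traj = make_traj([1.0], [0.5], unit_net)
        with pytest.raises(InsufficientDataError):
            dh_update_from_trajectory(traj, unit_net)


class TestDeltaUpdate:
    def test_no_net_change_gives_zero(self, unit_net):
        traj = make_traj([0.9, 0.1, 0.9], [0.3, 0.8, 0.3], unit_net)
        assert delta_update_from_trajectory(traj, unit_net).deltas[0][0, 0] == 0.0

    def test_direct_formula(self, unit_net):
        traj = make_traj([0.8, 0.8], [0.3, 0.7], unit_net)
        assert delta_update_from_trajectory(traj, unit_net).deltas[0][0, 0] == pytest.approx(0.32)


class TestBPReference:
    def test_zero_gradient_at_target(self, deep_net):
        x = np.array([0.3, 0.3, 0.3])
        y = feedforward_pass(deep_net, x)[-1]
        upd = bp_update_reference(deep_net, x, y)
        assert all(np.allclose(d, 0) for d in upd.deltas)

    def test_one_layer_linear_closed_form(self):
        net = LayeredNetwork((2, 1), [np.array([[0.4, -0.2]])], np.ones((1, 1)), "linear")
        x = np.array([0.5, 1.5])
        y = np.array([1.0])
        upd = bp_update_reference(net, x, y)
        yhat = net.W[0] @ x
        assert np.allclose(upd.deltas[0], np.outer(y - yhat, x))

    def test_matches_finite_differences(self, deep_net):
        """Central finite differences of the loss are the independent oracle."""
        x = np.array([0.9, 0.1, 0.5])
        y = np.array([0.8, 0.2])

        def loss(net):
            out = feedforward_pass(net, x)[-1]
            return 0.5 * np.sum((y - out) ** 2)

        upd = bp_update_reference(deep_net, x, y)
        h = 1e-6
        for l in range(len(deep_net.W)):
            fd = np.zeros_like(deep_net.W[l])
            for i in range(fd.shape[0]):
                for j in range(fd.shape[1]):
                    net2 = deep_net.copy()
                    net2.W[l][i, j] += h
                    lp = loss(net2)
                    net2.W[l][i, j] -= 2 * h
                    lm = loss(net2)
                    fd[i, j] = (lp - lm) / (2 * h)
            assert np.allclose(upd.deltas[l], -fd, rtol=1e-5, atol=1e-8)


class TestUpdateCorrelation:
    def test_perfect_linear_relation(self, rng):
        a = UpdateSet([rng.normal(size=(3, 4))], "DH")
        b = UpdateSet([2 * a.deltas[0]], "BP")
        assert update_correlation(a, b) == pytest.approx(1.0)

    def test_orthogonal_updates(self):
        a = UpdateSet([np.array([[1.0, -1.0, 1.0, -1.0]])], "DH")
        b = UpdateSet([np.array([[1.0, 1.0, -1.0, -1.0]])], "BP")
        assert update_correlation(a, b) == pytest.approx(0.0, abs=1e-12)

    def test_zero_variance_rejected(self):
        a = UpdateSet([np.ones((2, 2))], "DH")
        b = UpdateSet([np.ones((2, 2))], "BP")
        with pytest.raises(UndefinedCorrelationError):
            update_correlation(a, b)

    def test_matched_noise_gives_half_r2(self):
        """b = a + noise of equal variance -> R^2 ~ var_s/(var_s+var_n) = 0.5."""
        r2s = []
        for seed in range(100):
            g = np.random.default_rng(seed)
            sig = g.normal(size=200)
            a = UpdateSet([sig.reshape(10, 20)], "DH")
            b = UpdateSet([(sig + g.normal(size=200)).reshape(10, 20)], "BP")
            r2s.append(update_correlation(a, b))
        assert np.mean(r2s) == pytest.approx(0.5, abs=0.1)

    def test_regression_slope_sign(self, rng):
        a = UpdateSet([rng.normal(size=(5, 5))], "DH")
        b = UpdateSet([-3 * a.deltas[0]], "delta")
        slope, r2 = update_regression(a, b)
        assert slope == pytest.approx(-3.0) and r2 == pytest.approx(1.0)
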