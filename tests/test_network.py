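"""Rate dynamics: activations, open-loop fixed points, Euler integration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dhlearn.network import (
    ActivationFunction,
    ConfigurationError,
    LayeredNetwork,
    activation_apply,
    feedforward_pass,
    integrate_dynamics,
    open_loop_potentials,
)


class TestActivation:
    @pytest.mark.parametrize(
        "name,v,expected",
        [
            ("sigmoid", 0.0, 0.5),
            ("sigmoid", 2.0, 1.0 / (1.0 + np.exp(-2.0))),
            ("tanh", 0.0, 0.0),
            ("linear", -1.7, -1.7),
        ],
    )
    def test_forward_values(self, name, v, expected):
        assert activation_apply(name, np.array([v]))[0] == pytest.approx(expected, abs=1e-12)

    def test_tanh_derivative_at_zero(self):
        assert activation_apply("tanh", np.array([0.0]), derivative=True)[0] == pytest.approx(1.0)

    def test_unknown_name_rejected(self):
        with pytest.raises(ConfigurationError):
            ActivationFunction("relu")

    @pytest.mark.parametrize("name", ["sigmoid", "tanh", "linear"])
    def test_derivative_matches_finite_difference(self, name):
        v = np.linspace(-5, 5, 101)
        act = ActivationFunction(name)
        h = 1e-5
        fd = (act(v + h) - act(v - h)) / (2 * h)
        assert np.allclose(act(v, derivative=True), fd, atol=1e-6)


class TestFeedforward:
    def test_zero_weights_sigmoid_gives_half(self):
        net = LayeredNetwork((3, 4, 2), [np.zeros((4, 3)), np.zeros((2, 4))], np.zeros((6, 2)), "sigmoid")
        rates = feedforward_pass(net, np.array([0.3, 0.9, 0.1]))
        assert np.allclose(rates[1], 0.5) and np.allclose(rates[2], 0.5)

    def test_linear_identity_case(self):
        net = LayeredNetwork((1, 1), [np.array([[0.5]])], np.ones((1, 1)), "linear")
        assert feedforward_pass(net, np.array([1.0]))[1][0] == pytest.approx(0.5)

    def test_shape_mismatch_raises(self, small_net):
        with pytest.raises(ConfigurationError):
            feedforward_pass(small_net, np.zeros(5))

    def test_matches_long_open_loop_integration(self, small_net):
        """The cascade fixed point equals the relaxed Euler dynamics."""
        x = np.array([0.8, 0.2])
        rates = feedforward_pass(small_net, x)
        traj = integrate_dynamics(small_net, x, duration=40.0, dt=0.01)
        assert np.allclose(traj.r[-1], np.concatenate(rates), atol=1e-6)


class TestIntegration:
    def test_single_neuron_fixed_point(self, single_neuron_net):
        """v* = w_A r_A + w_B r_B with c = 0; r* = sigmoid(v*)."""
        traj = integrate_dynamics(single_neuron_net, np.array([1.0, 0.0]), duration=10.0, dt=0.01)
        assert traj.v[-1, 0] == pytest.approx(0.5, abs=1e-4)
        assert traj.r[-1, -1] == pytest.approx(1 / (1 + np.exp(-0.5)), abs=1e-4)

    def test_constant_feedback_fixed_point(self, small_net):
        """With c = c0 the equilibrium solves v = W r_pre + Q c0 self-consistently."""
        x = np.array([0.4, 0.6])
        c0 = np.array([0.3, -0.2])
        traj = integrate_dynamics(
            small_net, x, feedback_source=lambda t, v, r: c0, duration=60.0, dt=0.01
        )
        # damped fixed-point iteration as the independent oracle
        v = np.zeros(small_net.n_dynamic)
        for _ in range(20000):
            r = small_net.rates_from_state(x, v)
            v = 0.9 * v + 0.1 * (small_net.drive(r) + small_net.Q @ c0)
        assert np.allclose(traj.v[-1], v, atol=1e-6)

    def test_single_step_is_one_euler_update(self, small_net):
        x = np.array([0.1, 0.9])
        traj = integrate_dynamics(small_net, x, duration=0.02, dt=0.02, v0=None)
        v0 = np.zeros(small_net.n_dynamic)
        drive = small_net.drive(small_net.rates_from_state(x, v0))
        assert traj.n_steps == 2
        assert np.allclose(traj.v[1], v0 + 0.02 * (-v0 + drive))

    def test_input_layer_clamped(self, small_net):
        x = np.array([0.25, 0.75])
        traj = integrate_dynamics(small_net, x, duration=1.0, dt=0.1)
        assert np.all(traj.r[:, :2] == x)

    def test_rates_equal_phi_of_potentials(self, deep_net):
        traj = integrate_dynamics(deep_net, np.array([0.2, 0.5, 0.8]), duration=1.0, dt=0.05)
        assert np.allclose(traj.r[:, 3:], deep_net.activation(traj.v))

    def test_seeded_determinism_bitwise(self, small_net):
        kw = dict(noise_sd=0.5, duration=2.0, dt=0.02, seed=77)
        t1 = integrate_dynamics(small_net, np.array([0.5, 0.5]), **kw)
        t2 = integrate_dynamics(small_net, np.array([0.5, 0.5]), **kw)
        assert np.array_equal(t1.v, t2.v) and np.array_equal(t1.r, t2.r)

    def test_leak_decays_state_monotonically(self):
        net = LayeredNetwork((1, 2), [np.zeros((2, 1))], np.zeros((2, 2)), "linear")
        traj = integrate_dynamics(net, np.array([0.0]), duration=5.0, dt=0.1, v0=np.array([1.0, -2.0]))
        norms = np.linalg.norm(traj.v, axis=1)
        assert np.all(np.diff(norms) < 0)

    def test_euler_error_scales_linearly_with_dt(self, small_net):
        """Halving dt roughly halves the deviation from the dt->0 limit."""
        x = np.array([0.7, 0.3])
        ref = integrate_dynamics(small_net, x, duration=2.0, dt=0.0005).v[-1]
        e1 = np.linalg.norm(integrate_dynamics(small_net, x, duration=2.0, dt=0.04).v[-1] - ref)
        e2 = np.linalg.norm(integrate_dynamics(small_net, x, duration=2.0, dt=0.02).v[-1] - ref)
        assert e1 / e2 == pytest.approx(2.0, rel=1.0)  # within factor 4 of linear

    def test_equilibrium_start_is_stationary(self, deep_net):
        x = np.array([0.3, 0.6, 0.1])
        traj = integrate_dynamics(deep_net, x, duration=1.0, dt=0.02, v0="equilibrium")
        assert np.allclose(traj.v[0], traj.v[-1], atol=1e-10)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(0, 2**31 - 1))
def test_trajectory_invariants_random_nets(seed):
    """r = phi(v) at every step and shapes share the time axis."""
    rng = np.random.default_rng(seed)
    net = LayeredNetwork.init_random((2, 3, 1), seed=rng)
    x = rng.uniform(0, 1, 2)
    traj = integrate_dynamics(net, x, noise_sd=0.1, duration=0.5, dt=0.05, seed=rng)
    assert traj.v.shape[0] == traj.r.shape[0] == traj.c.shape[0] == len(traj.times)
    assert np.allclose(traj.r[:, 2:], net.activation(traj.v))
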