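import numpy as np
import pytest

from dhlearn.network import ActivationFunction, LayeredNetwork


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def single_neuron_net():
    """One sigmoid neuron with two inputs (w_A = 0.5, w_B = 0.3), unit feedback."""
    return LayeredNetwork((2, 1), [np.array([[0.5, 0.3]])], np.array([[1.0]]), "sigmoid")


@pytest.fixture
def small_net(rng):
    """Random 2-3-2 sigmoid network."""
    return LayeredNetwork.init_random((2, 3, 2), seed=rng)


@pytest.fixture
def deep_net(rng):
    """Random 3-4-4-2 sigmoid network."""
    return LayeredNetwork.init_random((3, 4, 4, 2), seed=rng)
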