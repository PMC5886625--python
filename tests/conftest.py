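import numpy as np
import pytest

from effconn import NetworkSpec, noise_free_precision, sample_er_network


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_network():
    """A sparse signed 20-node network in the standard strong-coupling regime."""
    spec = NetworkSpec(n_nodes=20, connection_prob=0.1, spectral_radius=0.7, seed=7)
    return sample_er_network(spec)


@pytest.fixture
def small_precision(small_network):
    return noise_free_precision(small_network)


def random_spd(n, rng, cond=10.0):
    """Random symmetric positive-definite matrix with moderate conditioning."""
    Q, _ = np.linalg.qr(rng.standard_normal((n, n)))
    evals = np.exp(np.linspace(0.0, np.log(cond), n))
    return (Q * evals) @ Q.T
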