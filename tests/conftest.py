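import numpy as np
import pytest

import netscale as ns
from netscale.core import Drive, NetworkSpec, NeuronParams

LIF_NEURON = NeuronParams(model="lif", tau_m=20, tau_s=2, tau_ref=2, theta=15, V_r=0)


@pytest.fixture(scope="session")
def asym_binary():
    """Two-population binary network with population-specific connectivity."""
    return ns.example_spec("asymmetric_binary")


@pytest.fixture(scope="session")
def asym_wp(asym_binary):
    return ns.mean_activity(asym_binary)


@pytest.fixture(scope="session")
def sym_binary():
    """Self-sustaining symmetric binary network (no external drive)."""
    return ns.example_spec("symmetric_binary")


@pytest.fixture(scope="session")
def two_pop_lif():
    return ns.example_spec("two_pop_lif")


@pytest.fixture(scope="session")
def lif_neuron():
    return LIF_NEURON


def small_lif_pair(sigma_ext=8.0, J_ext=0.3, d=0.1):
    """Small excitatory/inhibitory LIF network for simulation tests."""
    N = 1600
    K = 0.1 * N
    return NetworkSpec(
        populations=["e", "i"],
        N=[N, int(0.25 * N)],
        K=[[K, 0.25 * K], [K, 0.25 * K]],
        J=[[0.2, -1.0], [0.2, -1.0]],
        d=np.full((2, 2), d),
        neuron=[LIF_NEURON] * 2,
        drive=[Drive(kind="gaussian", mu_ext=16.0, sigma_ext=sigma_ext, J_ext=J_ext)] * 2,
    )


def random_stable_connectivity(rng, n, margin=0.3):
    """Random W with spectrum strictly left of 1."""
    W = rng.normal(0.0, 0.25, (n, n))
    lam = np.linalg.eigvals(W)
    shift = max(lam.real.max() - (1.0 - margin), 0.0)
    return W - shift * np.eye(n)
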