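import numpy as np
import pytest

from cosim.connectome import Connectome
from cosim.spiking import AdExParams, SpikingNetwork, SynapseParams


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def tiny_connectome():
    """Four regions, full weights, hand-set geometry."""
    W = np.array([
        [0.0, 0.5, 0.3, 0.2],
        [0.4, 0.0, 0.3, 0.3],
        [0.2, 0.2, 0.0, 0.6],
        [0.1, 0.4, 0.5, 0.0],
    ])
    centres = np.array([
        [0.0, 0.0, 0.0],
        [4.0, 0.0, 0.0],
        [0.0, 4.0, 0.0],
        [4.0, 4.0, 0.0],
    ])
    d = np.linalg.norm(centres[:, None] - centres[None, :], axis=2)
    return Connectome(
        weights=W, tract_lengths=d, centres=centres, spiking_regions=[0]
    )


def small_network(**overrides) -> SpikingNetwork:
    """An 80+20 neuron microcircuit with benign defaults for fast tests."""
    kw = dict(
        adex_ex=AdExParams(),
        adex_in=AdExParams(E_L=-65.0, Delta_T=0.5, tau_w=1.0, b=0.0),
        syn=SynapseParams(),
        n_ex=80,
        n_in=20,
        n_ext_synapses_per_neuron=0,
        seed=7,
    )
    kw.update(overrides)
    return SpikingNetwork(**kw)


@pytest.fixture
def cosim_tree():
    """A minimal but fully coupled co-simulation parameter tree."""
    return {
        "fixtures": {"n_regions": 6, "density": 0.6, "seed": 1},
        "spiking": {"n_ex": 40, "n_in": 10, "n_ext_synapses_per_neuron": 10,
                    "background_rate_hz": 400.0},
        "mass": {"init_rate_hz": 10.0, "params": {"noise_sigma": 1.0, "G": 0.3}},
        "run": {"t_end_ms": 20.0, "sync_step_ms": 2.0, "master_seed": 7,
                "backend": "threads", "run_dir": "unused"},
    }
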