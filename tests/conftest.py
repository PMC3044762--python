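import numpy as np
import pytest

import pairnet as pn
from pairnet.dynamics import IntegrationConfig, NoiseConfig, SpikeRecord


@pytest.fixture(scope="session")
def tiny_config():
    """A 50-neuron standard-regime network config for fast trials."""
    return pn.NetworkConfig(n_associative=50, input_probability=1 / 3,
                            groups_per_stimulus=6, master_seed=11)


@pytest.fixture()
def tiny_network(tiny_config):
    return pn.build_associative_network(tiny_config)


@pytest.fixture(scope="session")
def desk_integ():
    """Short desk-scale integration settings for unit tests."""
    return IntegrationConfig(dt=0.05, cue_ms=200.0, relax_ms=50.0)


@pytest.fixture(scope="session")
def no_noise():
    return NoiseConfig(voltage_noise_on=False, conductance_noise_on=False)


@pytest.fixture(scope="session")
def empty_inputs():
    return SpikeRecord(np.empty(0, dtype=np.int64), np.empty(0), "input", 200.0)


def zero_weights(network):
    for blk in network.blocks.values():
        blk.weights[...] = 0.0
    return network
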