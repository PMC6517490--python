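import numpy as np
import pytest

from biohybrid.params import (CultureParams, DetectorParams, NetworkConfig,
                              NeuronParams, STPParams, default_synapses)


@pytest.fixture
def neuron_params():
    return NeuronParams()


@pytest.fixture
def synapses():
    return default_synapses()


@pytest.fixture
def detector():
    return DetectorParams()


@pytest.fixture
def culture_params():
    return CultureParams()


@pytest.fixture
def scaled_config():
    """Degree-preserving 288-neuron scale-down of the full system."""
    return NetworkConfig.scaled(10)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
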