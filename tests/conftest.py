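import numpy as np
import pytest

from echoqc.model import NetworkConfig
from echoqc.phantom import DegradationConfig, default_plane_specs
from echoqc.planes import default_protocol


@pytest.fixture(scope="session")
def protocol():
    return default_protocol()


@pytest.fixture(scope="session")
def plane_specs():
    return default_plane_specs()


@pytest.fixture
def clean():
    return DegradationConfig()


@pytest.fixture
def tiny_config():
    """Smallest legal network: fast enough for per-test builds."""
    return NetworkConfig(
        encoder_widths=(2, 3, 4, 5, 6),
        decoder_widths=(5, 4, 3, 3, 2),
        stem_channels=2,
        n_structures=3,
        input_size=(32, 32),
    )


def rng(seed=0):
    return np.random.default_rng(seed)
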