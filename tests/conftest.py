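import numpy as np
import pytest

from striatnet import build_fsi_scaffold, build_msn_scaffold, build_network
from striatnet.netbuild import PlacementParams


@pytest.fixture(scope="session")
def msn_scaffold():
    return build_msn_scaffold()


@pytest.fixture(scope="session")
def fsi_scaffold():
    return build_fsi_scaffold()


@pytest.fixture(scope="session")
def small_network():
    """64-MSN network with cortical synapses; shared across tests."""
    return build_network(
        PlacementParams(n_per_side=4, seed=11), seed=11,
        lateral=True, feedforward=True, cortical=True,
    )


@pytest.fixture(scope="session")
def medium_network():
    """216-MSN network, wiring only (no cortical synapses)."""
    return build_network(
        PlacementParams(n_per_side=6, seed=7), seed=7,
        lateral=True, feedforward=True, cortical=False,
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(1234)
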