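import numpy as np
import pytest

import ephapsim as ep


@pytest.fixture(scope="session")
def hh():
    return ep.hh_model()


@pytest.fixture(scope="session")
def medium():
    return ep.ExtracellularMedium(0.3)


@pytest.fixture()
def single_sphere_net():
    """One spherical soma (r = 10 um), passive tag left to the test."""
    def make(model_tag):
        cell = ep.Cell("c")
        cell.add_section(ep.sphere("soma", 10.0, model_tag=model_tag))
        net = ep.Network()
        net.add(cell)
        return ep.discretize(net)
    return make


@pytest.fixture(scope="session")
def axon_net():
    return ep.fixture_network("axon")


def rng(seed=0):
    return np.random.default_rng(seed)
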