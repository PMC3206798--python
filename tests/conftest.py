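import pytest

from crowdflux.biophysics import default_params
from crowdflux.network import split_reversible
from crowdflux.synthetic import (ToySpec, assign_uniform_keff,
                                 make_core_network, make_toy_network)


@pytest.fixture(scope="session")
def params():
    return default_params()


@pytest.fixture(scope="session")
def toy_spec():
    return ToySpec()


@pytest.fixture(scope="session")
def toy_net(toy_spec):
    return make_toy_network(toy_spec)


@pytest.fixture(scope="session")
def core_net_standard():
    return make_core_network("standard")


@pytest.fixture(scope="session")
def core_net_net_zero():
    return make_core_network("net_zero")


@pytest.fixture(scope="session")
def core_lp_net_zero(core_net_net_zero):
    """Split, uniform-k_eff copy ready for the LP layer."""
    return assign_uniform_keff(split_reversible(core_net_net_zero), 600.0)


@pytest.fixture(scope="session")
def core_lp_standard(core_net_standard):
    return assign_uniform_keff(split_reversible(core_net_standard), 600.0)
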