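import pytest

from hepanet.scenarios import (
    make_cosubstrate_toy,
    make_liver_adipose_network,
    make_toy_networks,
)


@pytest.fixture(scope="session")
def toys():
    return make_toy_networks()


@pytest.fixture(scope="session")
def chain(toys):
    return toys["chain"]


@pytest.fixture(scope="session")
def branch2(toys):
    return toys["branch2"]


@pytest.fixture(scope="session")
def feedback_loop(toys):
    return toys["feedback_loop"]


@pytest.fixture(scope="session")
def cosub_toy():
    return make_cosubstrate_toy(0.3)


@pytest.fixture(scope="session")
def liver_net():
    return make_liver_adipose_network()
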