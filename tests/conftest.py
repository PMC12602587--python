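import numpy as np
import pytest

from isingselect import FixtureSpec, make_toy_network, make_true_network


@pytest.fixture(scope="session")
def fixture9():
    """The 9-node all-positive data-generating network (default FixtureSpec)."""
    return make_true_network(FixtureSpec())


@pytest.fixture(scope="session")
def pair_model():
    return make_toy_network("pair-ln2")


@pytest.fixture(scope="session")
def triple_model():
    return make_toy_network("triple-uniform")


@pytest.fixture(scope="session")
def chain_model():
    return make_toy_network("five-chain")


@pytest.fixture
def rng():
    return np.random.default_rng(20260923)
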