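import numpy as np
import pytest

from cpeopt import cpe_screening_space, load_fixture, train


@pytest.fixture(scope="session")
def space():
    return cpe_screening_space()


@pytest.fixture(scope="session")
def table2():
    return load_fixture("table2")


@pytest.fixture(scope="session")
def table2_model(table2):
    """Identity-activation reference fit to the screening table."""
    return train(table2, 7, ("identity", "identity"), seed=1)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
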