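import numpy as np
import pytest

from xbridge import load_preset


@pytest.fixture(scope="session")
def standard():
    return load_preset("standard_30C")


@pytest.fixture(scope="session")
def optimized():
    return load_preset("optimized_30C")


@pytest.fixture(scope="session")
def optimized_22C():
    return load_preset("optimized_22C")


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def iso_distribution(optimized):
    """Isometric distribution of the optimized set, shared across tests."""
    from xbridge import solve_isometric

    return solve_isometric(optimized)
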