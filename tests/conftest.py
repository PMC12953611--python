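import numpy as np
import pytest

from irute.phantom import default_tissue_table, make_phantom
from irute.recon import GriddingParams
from irute.sequence import SequenceParams


@pytest.fixture(scope="session")
def tissues():
    """Default tissue table keyed by class name."""
    return {c.name: c for c in default_tissue_table()}


@pytest.fixture(scope="session")
def sim_params():
    """The 2D simulation acquisition protocol."""
    return SequenceParams()


@pytest.fixture(scope="session")
def gp():
    return GriddingParams()


@pytest.fixture(scope="session")
def small_phantom():
    return make_phantom(size=64, seed=3, n_lesions=2)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
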