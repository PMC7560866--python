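import numpy as np
import pytest

import priorcut as pc


@pytest.fixture(scope="session")
def pathway():
    """50-node / 60-edge pathway-like graph used throughout the suite."""
    return pc.random_pathway(50, 60, "chain_lattice", seed=1)


@pytest.fixture(scope="session")
def ggm(pathway):
    """Ground-truth GGM on the pathway with nominal edge |pcor| 0.25."""
    return pc.ggm_from_graph(pathway, 0.25, seed=1)


@pytest.fixture(scope="session")
def fixture_data(ggm):
    """600 complete samples drawn from the fixture model."""
    x, _ = pc.sample_data(ggm, 600, seed=1)
    return x


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
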