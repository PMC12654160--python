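import numpy as np
import pytest

import soilpem as sp
from soilpem.simulate import GeneratorConfig

SMALL_RICHNESS = {"bacteria": 40, "fungi": 20, "archaea": 10}
SMALL_DEPTH = {"bacteria": 2000, "fungi": 1000, "archaea": 500}


@pytest.fixture(scope="session")
def small_config():
    return GeneratorConfig(seed=11, richness=SMALL_RICHNESS, depth=SMALL_DEPTH)


@pytest.fixture(scope="session")
def small_dataset(small_config):
    """Default 5x4 design with reduced OTU richness for speed."""
    return sp.generate_dataset(small_config)


@pytest.fixture(scope="session")
def big_replicate_dataset():
    """200 replicates per treatment: enough for mean-ratio convergence."""
    cfg = GeneratorConfig(seed=23, n_replicates=200,
                          richness={"bacteria": 10, "fungi": 5, "archaea": 5},
                          depth={"bacteria": 500, "fungi": 300, "archaea": 200})
    return sp.generate_dataset(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


def random_distance(n, rng):
    m = np.abs(rng.standard_normal((n, n)))
    m = (m + m.T) / 2.0
    np.fill_diagonal(m, 0.0)
    return m
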