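import numpy as np
import pytest

import iclipkit as ik


@pytest.fixture(scope="session")
def small_simulation():
    """One small seeded simulation shared by read-level tests."""
    config = ik.SimulationConfig(n_genes=6, seed=1)
    genome, annotation, truth = ik.simulate_genome(config)
    return config, genome, annotation, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
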