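import numpy as np
import pytest

from mdtips import synthetic, workflows


@pytest.fixture(scope="session")
def tiny_world():
    """Small coherent world for fast unit tests."""
    config = synthetic.SimConfig(n_drugs=16, n_targets=20,
                                 n_kg_extra_entities=8, G=10,
                                 positive_rate=0.15, seed=3)
    return synthetic.simulate_world(config)


@pytest.fixture(scope="session")
def tiny_resources(tiny_world):
    return workflows.build_resources(
        tiny_world, workflows.desk_kge_config(seed=0, epochs=40),
        max_len=32, n_merges=20)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
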