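import numpy as np
import pytest

from rhizosge import SimulationConfig, simulate_experiment


@pytest.fixture(scope="session")
def small_dataset():
    """A compact simulated experiment (4 strains x 3 blocks) with CFU data."""
    cfg = SimulationConfig(n_strains=4, n_blocks=3, n_controls_per_block=1, seed=42)
    return simulate_experiment(cfg)


@pytest.fixture(scope="session")
def paper_scale_dataset():
    """A full-size simulated experiment (8 strains x 8 blocks, 592 pots)."""
    return simulate_experiment(SimulationConfig(seed=7))


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240101)
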