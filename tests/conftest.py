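import numpy as np
import pytest

from probenet.simulate import (MicrobeSpec, SimulationConfig, random_sequence,
                               simulate_study)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240915)


def make_seq(seed: int, length: int) -> str:
    return random_sequence(np.random.default_rng(seed), length)


@pytest.fixture(scope="session")
def study():
    """One-sample synthetic study with two microbes at known abundances."""
    cfg = SimulationConfig(
        rng_seed=7,
        host_cell_count=10.0,
        microbes=[
            MicrobeSpec("Bacillus simulans", "B1", 0.1, rbpc=2000.0),
            MicrobeSpec("Fungus simulans", "F2", 0.05, rbpc=10000.0),
        ],
        reads_per_sample=3000,
    )
    return simulate_study(cfg)
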