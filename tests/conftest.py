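import numpy as np
import pytest

from duplexprof import generate_genome, simulate_duplex_experiment
from duplexprof.simulate import SimulationConfig


@pytest.fixture(scope="session")
def small_genome():
    return generate_genome(5_000, gc_fraction=0.5, seed=11)


@pytest.fixture(scope="session")
def medium_genome():
    return generate_genome(50_000, gc_fraction=0.5, seed=12)


@pytest.fixture(scope="session")
def clean_run(medium_genome):
    """A small error-free, mutation-free simulated library."""
    config = SimulationConfig(n_fragments=400, seed=21)
    pairs, truth = simulate_duplex_experiment(medium_genome, config)
    return pairs, truth, config


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
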