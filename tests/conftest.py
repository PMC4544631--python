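import numpy as np
import pytest

from gsel.simulate import (
    random_cross_plan,
    simulate_founders,
    simulate_population,
    uniform_map,
)


@pytest.fixture(scope="session")
def small_map():
    """3 chromosomes x 100 cM, 30 evenly spaced markers each."""
    return uniform_map(n_chromosomes=3, chrom_length_cM=100.0, markers_per_chromosome=30)


@pytest.fixture(scope="session")
def founders(small_map):
    return simulate_founders(20, small_map, seed=11)


@pytest.fixture(scope="session")
def dh_pop(founders):
    plan = random_cross_plan(founders.parent_ids, 12, 10, line_type="DH", seed=3)
    return simulate_population(founders, plan, seed=4, population_id="dh")


@pytest.fixture
def rng():
    return np.random.default_rng(20260921)
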