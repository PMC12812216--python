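import numpy as np
import pytest

from voomclr import CountMatrix, DesignMatrix
from voomclr.simulate import SimulationConfig, simulate_dirichlet_multinomial


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def two_group_design():
    def make(n_per_group):
        n = 2 * n_per_group
        vals = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n_per_group)])
        return DesignMatrix(values=vals, column_names=["Intercept", "group"])

    return make


@pytest.fixture
def small_counts(rng):
    """10 samples x 6 populations of Poisson counts around distinct means."""
    means = np.array([5, 20, 50, 120, 400, 1000])
    vals = rng.poisson(means, size=(10, 6))
    return CountMatrix(
        values=vals,
        sample_ids=[f"s{i}" for i in range(10)],
        population_ids=[f"p{j}" for j in range(6)],
    )


@pytest.fixture
def dm_dataset():
    """Default-scenario Dirichlet-Multinomial dataset (P=11, n=20/group)."""
    return simulate_dirichlet_multinomial(SimulationConfig(seed=11))
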