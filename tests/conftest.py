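import numpy as np
import pandas as pd
import pytest

from spdprog.config import RunConfig
from spdprog.synth import simulate_progression


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture(scope="session")
def linear_data():
    """Small planted linear progression shared across tests."""
    expr, truth = simulate_progression(
        n_samples=12, n_prog_modules=3, genes_per_module=10,
        n_noise_genes=30, noise_sd=0.05, seed=7,
    )
    return expr, truth


@pytest.fixture(scope="session")
def star_data():
    expr, truth = simulate_progression(
        topology={"arms": 3, "arm_length": 4}, n_prog_modules=6,
        genes_per_module=12, n_noise_genes=30, noise_sd=0.05, seed=7,
    )
    return expr, truth


@pytest.fixture
def small_cfg():
    """Fast configuration for pipeline tests."""
    return RunConfig(kmeans_runs=30, n_permutations=500, p_threshold=0.004, seed=7)


def random_distance_matrix(n, rng):
    """Euclidean distance matrix of random points (distinct with prob. 1)."""
    from scipy.spatial.distance import pdist, squareform

    pts = rng.normal(size=(n, 3))
    d = squareform(pdist(pts))
    ids = [f"s{i}" for i in range(n)]
    return pd.DataFrame(d, index=ids, columns=ids)
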