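import numpy as np
import pytest
from hypothesis import settings

import dmoiob as dm

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """A deterministic 8x5 matrix with one exactly additive 4x3 corner."""
    rng = np.random.default_rng(7)
    values = rng.uniform(0, 600, size=(8, 5))
    mu, alpha, beta = 300.0, np.array([0.0, 40.0, -30.0, 10.0]), np.array([0.0, 25.0, -15.0])
    values[:4, :3] = mu + alpha[:, None] + beta[None, :]
    return dm.ExpressionMatrix(
        values,
        [f"g{i}" for i in range(8)],
        [f"c{j}" for j in range(5)],
    )


@pytest.fixture
def planted_100x20():
    """100x20 yeast-like matrix with a noiseless additive 20x8 plant."""
    M, truth = dm.generate(
        100, 20,
        [dm.PlantedBicluster(np.arange(20), np.arange(8), noise_sd=0.0)],
        rng=11,
    )
    return M, truth


def random_objectives(rng, k, feasible=True):
    vals = rng.random((k, 3))
    return [dm.ObjectiveVector(v, feasible) for v in vals]
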