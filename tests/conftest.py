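import numpy as np
import pytest

from sigmoid.datatypes import BinaryDataset, FeatureMatrix, FitConfig, LatentMatrix
from sigmoid.simulate import generate_dataset, generate_parameters


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_model(rng):
    """A random 5-sample x 6-variable, K=2 parameter pair."""
    beta = LatentMatrix(rng.normal(0, 1, (5, 2)))
    energies = FeatureMatrix(rng.normal(0, 1, (2, 6)))
    return beta, energies


@pytest.fixture(scope="session")
def planted_bundle():
    """Planted model and dataset used by recovery-style tests (S=200, N=50, K=3)."""
    latents, features = generate_parameters(200, 50, 3, 1.0, 1.0, seed=11)
    return generate_dataset(latents, features, seed=12)


@pytest.fixture(scope="session")
def planted_fit(planted_bundle):
    from sigmoid.model import fit

    return fit(planted_bundle.data, FitConfig(K=3, seed=1, tol=1e-9, max_iters=4000))


def random_dataset(rng, S, N):
    return BinaryDataset((rng.random((S, N)) < 0.5).astype(int))
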