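import numpy as np
import pytest

from morphnet.atlas import load_atlas
from morphnet.cohort import CohortSpec, generate_cohort
from morphnet.io import zscore_features


@pytest.fixture(scope="session")
def atlas():
    return load_atlas()


@pytest.fixture(scope="session")
def small_cohort():
    """5 + 5 subjects, 68 regions, 5 features; deterministic."""
    spec = CohortSpec(n_nc=5, n_ad=5, seed=11)
    tensor, cohort = generate_cohort(spec)
    return tensor, cohort


@pytest.fixture(scope="session")
def ztensor(small_cohort):
    tensor, _ = small_cohort
    return zscore_features(tensor)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def random_weight_matrix(rng, n, density=0.7):
    """Random symmetric nonnegative weight matrix with zero diagonal."""
    w = rng.uniform(0.05, 1.0, size=(n, n))
    mask = rng.random((n, n)) < density
    w = np.triu(w * mask, 1)
    w = w + w.T
    return w
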