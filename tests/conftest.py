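import numpy as np
import pytest

from spinlm import CovarianceSpec, SpatialDataset, build_cov_matrix


@pytest.fixture
def rng():
    return np.random.default_rng(1729)


@pytest.fixture
def exp_spec():
    return CovarianceSpec("exponential", 2.0, 0.3, 0.4)


def make_gaussian_dataset(n, spec, seed, beta=(1.0, 2.0), coords=None):
    """Small dataset drawn exactly from the stated covariance model."""
    rng = np.random.default_rng(seed)
    if coords is None:
        coords = rng.uniform(0.0, 1.0, size=(n, 2))
    x = np.column_stack([np.ones(n), rng.standard_normal(n)])
    v = build_cov_matrix(coords, spec, check=False)
    y = x @ np.asarray(beta) + np.linalg.cholesky(v) @ rng.standard_normal(n)
    return SpatialDataset(coords, x, y), v


@pytest.fixture
def small_dataset(exp_spec):
    dataset, _ = make_gaussian_dataset(80, exp_spec, seed=5)
    return dataset
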