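import numpy as np
import pytest

from egadim import (
    CorrelationMatrix,
    FactorDesign,
    population_model,
    simulate_binary,
)


@pytest.fixture(scope="session")
def two_factor_orthogonal():
    """Population model for 2 factors x 5 items, orthogonal."""
    design = FactorDesign(n_factors=2, items_per_factor=5, factor_corr=0.0,
                          n_obs=1000)
    return design, population_model(design)


@pytest.fixture(scope="session")
def four_factor_correlated():
    """Population model for 4 factors x 5 items, rho = .7."""
    design = FactorDesign(n_factors=4, items_per_factor=5, factor_corr=0.7,
                          n_obs=5000)
    return design, population_model(design)


def population_correlation(model, n_obs=1000):
    """Wrap a population latent correlation matrix for pipeline input."""
    return CorrelationMatrix(values=model.correlation, method="tetrachoric",
                             n_obs=n_obs)


@pytest.fixture(scope="session")
def binary_sample_2f():
    """One simulated dataset: 2 orthogonal factors, 5 items each, n=5000."""
    design = FactorDesign(n_factors=2, items_per_factor=5, factor_corr=0.0,
                          n_obs=5000, seed=123)
    return design, simulate_binary(design)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
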