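import numpy as np
import pytest

from sdmbench.grids import GridSpec
from sdmbench.landscape import (
    enumerate_term_pool,
    generate_covariates,
    predict_truth_surface,
    sample_validation_points,
    SpeciesModel,
    Term,
)


@pytest.fixture(scope="session")
def grid():
    return GridSpec(40, 20)


@pytest.fixture(scope="session")
def covariates(grid):
    return generate_covariates(grid, n_cov=3, rng_seed=11)


@pytest.fixture(scope="session")
def truth(covariates):
    """A fixed species with a gentle response to the first two layers."""
    model = SpeciesModel(
        terms=[Term("linear", 0), Term("square", 1)],
        coefficients=np.array([2.0, -1.5]),
        intercept=0.5,
    )
    return predict_truth_surface(model, covariates, noise_sd=0.25, rng_seed=5)


@pytest.fixture(scope="session")
def validation(truth):
    return sample_validation_points(truth, n=400, rng_seed=7)
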