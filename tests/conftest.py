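import numpy as np
import pytest

from meanmatch import IncompleteSample, fit_imputation_model
from meanmatch.simulation import generate_study1, impose_mcar


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def tiny_sample():
    """Three observed cases (exact-fit free), two recipients."""
    x = np.array([0.0, 0.0, 3.0, np.nan, np.nan])
    y = np.array([0.0, 1.0, 2.0, 0.5, 1.5])
    return IncompleteSample.from_xy(x, y)


@pytest.fixture
def study1_sample():
    """A realistic correctly-specified dataset with ~25% MCAR missingness."""
    rng = np.random.default_rng(7)
    x, y = generate_study1(400, 3.33, rng)
    return impose_mcar(x, y, 0.25, rng)


@pytest.fixture
def study1_fit(study1_sample):
    return fit_imputation_model(study1_sample)
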