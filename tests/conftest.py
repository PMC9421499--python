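import numpy as np
import pytest

from healthexp.cohort import default_true_params, generate_cohort, preset


@pytest.fixture(scope="session")
def true_params():
    return default_true_params()


@pytest.fixture(scope="session")
def obese_params():
    """Generator truth with a single active covariate (obesity)."""
    return default_true_params(covariates=("obese",))


@pytest.fixture(scope="session")
def small_cohort(obese_params):
    """A small but fully featured synthetic panel (jitter, non-response,
    deaths) for fast model-level tests."""
    cfg = preset("cohort1921", n_individuals=400, seed=7,
                 true_params=obese_params,
                 covariate_prevalences={"obese": 0.25})
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_fit(small_cohort):
    from healthexp.model import DisabilityMarkovModel
    return DisabilityMarkovModel(small_cohort, covariates=("obese",),
                                 age_center=70.0).fit()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
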