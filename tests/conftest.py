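import numpy as np
import pytest

from sf6dmap import generate_cohort, make_synthetic_tariff


@pytest.fixture(scope="session")
def tariff():
    return make_synthetic_tariff(0)


@pytest.fixture(scope="session")
def cohort(tariff):
    """Mid-sized synthetic cohort shared across estimator tests."""
    return generate_cohort(tariff=tariff, n=600, seed=11)


@pytest.fixture(scope="session")
def big_cohort(tariff):
    """Larger cohort for calibration / recovery checks."""
    return generate_cohort(tariff=tariff, n=2000, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
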