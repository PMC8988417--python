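import numpy as np
import pytest

from hetsurv import DGMConfig, fit_cox, generate_cohort


@pytest.fixture(scope="session")
def nocens_cohort():
    """Moderate uncensored cohort from the default generating mechanism."""
    return generate_cohort(DGMConfig(n=50_000, seed=101))


@pytest.fixture(scope="session")
def admin_cohort():
    """Administratively censored cohort (cap at t = 15)."""
    return generate_cohort(
        DGMConfig(n=50_000, censoring_mode="administrative", seed=102)
    )


@pytest.fixture(scope="session")
def random_cens_cohort():
    """Randomly censored cohort (plus the administrative cap)."""
    return generate_cohort(DGMConfig(n=50_000, censoring_mode="random", seed=103))


@pytest.fixture(scope="session")
def small_censored_cohort():
    """Tiny censored cohort for brute-force oracle comparisons."""
    return generate_cohort(DGMConfig(n=150, censoring_mode="random", seed=7))


@pytest.fixture(scope="session")
def cox_model(admin_cohort):
    return fit_cox(admin_cohort, ["x"])
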