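import numpy as np
import pytest

from adjiv import (
    CovariateMarginals,
    HospitalConfig,
    CoefficientConfig,
    simulate_dataset,
)


@pytest.fixture(scope="session")
def default_marginals():
    return CovariateMarginals()


@pytest.fixture(scope="session")
def small_hospitals():
    return HospitalConfig(n_hospitals=20, patients_per_hospital=150)


@pytest.fixture(scope="session")
def rct_dataset(small_hospitals):
    """One moderate RCT-scenario cohort (treatment randomized)."""
    return simulate_dataset(
        n_patients=3000, hospital_config=small_hospitals, scenario=2, seed=42
    )


@pytest.fixture(scope="session")
def confounded_dataset(small_hospitals):
    """One moderate cohort with measured+unmeasured confounding and preference."""
    return simulate_dataset(
        n_patients=3000, hospital_config=small_hospitals, scenario=6, seed=43
    )


@pytest.fixture(scope="session")
def zero_coefs():
    """Coefficient config with every covariate and treatment effect zeroed."""
    return CoefficientConfig(
        beta_CT={}, beta_UT={}, beta_CY={}, beta_UY={}, beta_T=0.0, alpha_T=0.0
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20251001)
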