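import numpy as np
import pytest

import skintact as sk


@pytest.fixture(scope="session")
def small_cohort():
    """Study-sized cohort (60 participants), fixed seed."""
    return sk.generate_cohort(sk.CohortConfig(n_participants=60, seed=11))


@pytest.fixture(scope="session")
def large_cohort():
    """Large cohort for closure checks of population-level statistics."""
    return sk.generate_cohort(sk.CohortConfig(n_participants=10_000, seed=5))


@pytest.fixture(scope="session")
def large_mu(large_cohort):
    return sk.generate_friction_coefficients(
        large_cohort, sk.FrictionModelConfig(seed=6)
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
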