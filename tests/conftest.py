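import numpy as np
import pytest

from vaforecast import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """A 12-patient synthetic cohort with small images, shared across tests."""
    cfg = CohortConfig(n_patients=12, seed=42, image_size=32)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture(scope="session")
def quiet_cohort():
    """Low-noise cohort where the VA law is nearly deterministic."""
    cfg = CohortConfig(n_patients=40, seed=7, va_noise_sd=0.005, image_size=32)
    cohort, truth = generate_cohort(cfg)
    return cfg, cohort, truth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
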