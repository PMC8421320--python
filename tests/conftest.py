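import numpy as np
import pytest

from dualflow import CohortConfig, simulate_cohort


@pytest.fixture(scope="session")
def noiseless_config() -> CohortConfig:
    """Two-subject homogeneous cohort with all noise sources off."""
    return CohortConfig(n_subjects=2, seed=11, pet_noise_scale=0.0,
                        mri_snr=float("inf"), segment_heterogeneity_cv=0.0)


@pytest.fixture(scope="session")
def noiseless_cohort(noiseless_config):
    return simulate_cohort(noiseless_config)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)
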