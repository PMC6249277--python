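import numpy as np
import pytest

from glauprog import SynthConfig, builtin_maps, generate_cohort


@pytest.fixture(scope="session")
def maps():
    return builtin_maps()


@pytest.fixture(scope="session")
def small_cohort():
    """A small noisy cohort shared across read-only tests."""
    return generate_cohort(SynthConfig(n_subjects=10, seed=42))


@pytest.fixture(scope="session")
def noise_free_config():
    """All noise and heterogeneity off: every eye follows the mean lines."""
    return SynthConfig(
        n_subjects=8, bilateral_fraction=0.5, vf_point_noise_sd=0.0,
        oct_sector_noise_sd=0.0, between_eye_variance_fraction=0.0,
        slope_md_sd=0.0, slope_rnflt_sd=0.0, baseline_md_sd=0.0,
        baseline_rnflt_sd=0.0, slope_rnflt_sector_sd=0.0,
        slope_md_sector_sd=0.0, seed=7)


@pytest.fixture(scope="session")
def noise_free_cohort(noise_free_config):
    return generate_cohort(noise_free_config)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
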