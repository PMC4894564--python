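import numpy as np
import pytest

from scleromech.cohort import GeneratorConfig, generate_cohort


@pytest.fixture(scope="session")
def noise_free_cohort():
    """Small cohort with all residual SDs zero: every value on its line."""
    return generate_cohort(4, 4, seed=11, config=GeneratorConfig.noise_free())


@pytest.fixture(scope="session")
def default_cohort():
    """Study-scale cohort (15 affected / 10 normal) at default calibration."""
    return generate_cohort(15, 10, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
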