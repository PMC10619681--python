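import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from hpglyco.synth import GeneratorConfig, generate_cohort

settings.register_profile(
    "deterministic",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def tiny_config():
    """8-sample, 20-glycoform cohort configuration for fast unit tests."""
    return GeneratorConfig(
        n_control=3,
        n_early=3,
        n_late=2,
        site_glycoforms={"N184": 5, "N207": 5, "N211": 5, "N241": 5},
        seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_config):
    return generate_cohort(tiny_config)


@pytest.fixture(scope="session")
def study_cohort():
    """Study-shaped cohort: 57/50/32 samples, 36/42/31/50 glycoforms."""
    return generate_cohort(GeneratorConfig(seed=5))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
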