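import pytest

from dgquant.config import GeneratorConfig
from dgquant.synth import generate_cohort, generate_study


@pytest.fixture(scope="session")
def default_config() -> GeneratorConfig:
    return GeneratorConfig(seed=7)


@pytest.fixture(scope="session")
def default_cohort(default_config):
    return generate_cohort(default_config)


@pytest.fixture(scope="session")
def small_config() -> GeneratorConfig:
    """One-batch study: 24 mice, 8 cages, 8 IHC animals."""
    return GeneratorConfig(seed=11, n_batches=1)


@pytest.fixture(scope="session")
def small_study(small_config):
    return generate_study(small_config)
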