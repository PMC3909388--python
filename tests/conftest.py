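import pytest
from hypothesis import HealthCheck, settings

from cohortflow import GeneratorConfig

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=80,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def config():
    return GeneratorConfig(seed=123)


@pytest.fixture
def criteria(config):
    return config.criteria
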