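import pytest
from hypothesis import HealthCheck, settings

from bqindex import load_rda_table, load_taxonomy

settings.register_profile(
    "default",
    max_examples=50,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def taxonomy():
    return load_taxonomy()


@pytest.fixture(scope="session")
def rda():
    return load_rda_table()
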