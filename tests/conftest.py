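import pytest
from hypothesis import HealthCheck, settings

from oncoextract import HashingNgramEmbedder, default_registry

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def embedder():
    return HashingNgramEmbedder()
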