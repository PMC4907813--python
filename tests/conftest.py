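import pytest
from hypothesis import HealthCheck, settings

from splicepriors import generate_toy_gene

settings.register_profile(
    "deterministic",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("deterministic")


@pytest.fixture(scope="session")
def toy():
    """Standard three-exon toy-gene fixture."""
    return generate_toy_gene(seed=7)


@pytest.fixture(scope="session")
def og(toy):
    return toy.oriented()
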