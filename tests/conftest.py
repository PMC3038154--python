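import pytest
from hypothesis import settings

from fluxseries import fixtures

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def chain():
    return fixtures.make_chain(3)


@pytest.fixture
def parallel():
    return fixtures.make_parallel()


@pytest.fixture
def loop():
    return fixtures.make_loop()


@pytest.fixture
def leaky():
    return fixtures.make_leaky()
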