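import pytest

from rrmbindkit import fixtures


@pytest.fixture(scope="session")
def model():
    return fixtures.fixture_model()


@pytest.fixture(scope="session")
def rrm1():
    return fixtures.rrm1_profile()


@pytest.fixture(scope="session")
def rrm2():
    return fixtures.rrm2_profile()
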