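import pytest

from flexsite import simulate as sim


@pytest.fixture(scope="session")
def fixture_bundle():
    """The deterministic worked fixture shared by oracle tests."""
    return sim.worked_fixture()


@pytest.fixture(scope="session")
def pfms():
    return sim.builtin_pfms()
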