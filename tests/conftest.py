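import pytest
from hypothesis import settings

from tfamm.exposure import DEFAULT_GRID
from tfamm.fixtures import make_brazil_fixture

settings.register_profile("suite", max_examples=50, deadline=None,
                          derandomize=True)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def brazil():
    """The calibrated Brazil-2018-like fixture (built once per session)."""
    return make_brazil_fixture()


@pytest.fixture(scope="session")
def grid():
    return DEFAULT_GRID
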