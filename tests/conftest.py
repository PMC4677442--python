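import pytest

from lysisgate import default_catalog, make_mock_cases


@pytest.fixture(scope="session")
def catalog():
    return default_catalog()


@pytest.fixture(scope="session")
def mock_cases():
    """The four canonical mock records and their code-stroke index time."""
    return make_mock_cases()
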