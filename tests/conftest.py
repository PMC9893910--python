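import pytest

from fefkit import load_fixtures


@pytest.fixture(scope="session")
def fx():
    """Bundled coefficient tables and published scenario outputs."""
    return load_fixtures()
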