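import pytest

from qmarker import load_default_library, load_default_panel


@pytest.fixture(scope="session")
def library():
    return load_default_library()


@pytest.fixture(scope="session")
def panel():
    return load_default_panel()
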