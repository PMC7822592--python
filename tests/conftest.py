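import pytest

from ocnforms import builtin_protein, default_alphabet


@pytest.fixture(scope="session")
def mouse():
    return builtin_protein("mouse")


@pytest.fixture(scope="session")
def human():
    return builtin_protein("human")


@pytest.fixture(scope="session")
def mouse_alphabet(mouse):
    return default_alphabet(mouse)
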