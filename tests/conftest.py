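import pytest

from stomasim import guard_cell_model, toy_models


@pytest.fixture(scope="session")
def guard_cell():
    """The packaged synthetic guard-cell model (session-cached)."""
    return guard_cell_model()


@pytest.fixture(scope="session")
def toys():
    return toy_models()
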