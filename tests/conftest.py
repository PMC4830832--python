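import pytest

from boolfate.core import BooleanNetwork
from boolfate.pc12 import load_fixture


@pytest.fixture
def negative_loop():
    """Two-node negative feedback loop: B := A, A := !B."""
    return BooleanNetwork(["A", "B"], {"A": "!B", "B": "A"})


@pytest.fixture(scope="session")
def final_model():
    return load_fixture("final")


@pytest.fixture(scope="session")
def pc12_pkn():
    return load_fixture("pkn")
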