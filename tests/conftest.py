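import pytest

from basefive import parse_explicit


@pytest.fixture
def eq2a():
    """CTGATAAC with dense places 1..8 (the basic worked vector)."""
    return parse_explicit("CTGATAAC")


@pytest.fixture
def eq2b():
    """The same bases after two E insertions: C1 T2 E3 G4 A5 T6 E7 E8 A9 A10 C11."""
    return parse_explicit("C1 T2 E3 G4 A5 T6 E7 E8 A9 A10 C11")
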