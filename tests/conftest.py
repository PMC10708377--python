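import pytest

import pisawheel as pw


@pytest.fixture(scope="session")
def syd4():
    """The 57-residue syndecan-4 ecto/TM/cyto construct."""
    return pw.make_construct(pw.SYD4_ETC_SEQUENCE)


@pytest.fixture(scope="session")
def tm_helix():
    """Ideal helix covering the TM segment (25 amide sites)."""
    return pw.build_helix(-69.0, -42.0, 26)


@pytest.fixture(scope="session")
def canonical_helix():
    return pw.build_helix(-57.8, -47.0, 20)


@pytest.fixture(scope="session")
def n15():
    return pw.N15_TENSOR


@pytest.fixture(scope="session")
def bicelle():
    """Unflipped bicelle at the study's upper order parameter."""
    return pw.BicelleModel(order_parameter=0.85, flip="unflipped")
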