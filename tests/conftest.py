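import pytest

from camkin import AquaComplex, AssayConditions


@pytest.fixture(scope="session")
def default_conditions() -> AssayConditions:
    return AssayConditions()


@pytest.fixture(scope="session")
def zinc_complex() -> AquaComplex:
    return AquaComplex("1", "Zn", 8.0)
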