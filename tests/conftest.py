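import pytest

from pmfsim import CRingConfig, KineticParams, ThermoParams


@pytest.fixture(scope="session")
def thermo():
    return ThermoParams()


@pytest.fixture(scope="session")
def params():
    return KineticParams()


@pytest.fixture(scope="session")
def ring14():
    return CRingConfig(14)


@pytest.fixture(scope="session")
def ring8():
    return CRingConfig(8)
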