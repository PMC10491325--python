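import pytest

from acamech import ConstitutiveParams, ReferenceGeometry


@pytest.fixture
def geom() -> ReferenceGeometry:
    """Reference geometry in the human-ACA size range."""
    return ReferenceGeometry(Ro=1.30, Ri=1.00, L=12.0)


@pytest.fixture
def params() -> ConstitutiveParams:
    """Default forward constitutive model (a=5 kPa, b=12, lz*=1.12)."""
    return ConstitutiveParams()
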