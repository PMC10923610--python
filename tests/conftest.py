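import pytest
from hypothesis import settings

from shearpick.flow_core import FluidProperties, PlateChannel
from shearpick.ptms_design import PTMSGeometry

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def fluid():
    """Water-like medium, mu = 1 mPa.s."""
    return FluidProperties()


@pytest.fixture(scope="session")
def channel():
    """The characterisation flow chamber: 30 x 3.5 x 0.25 mm."""
    return PlateChannel(length=30.0, width=3.5, height=0.25)


@pytest.fixture(scope="session")
def geometry():
    """Reference pin geometry: r0 = 500 um, h0 = 50 um, bore 150 um."""
    return PTMSGeometry()
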