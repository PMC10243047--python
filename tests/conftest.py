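import pytest
from hypothesis import settings

from bioshear import AgitationCondition, FluidProperties, VesselGeometry

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def reference_geometry() -> VesselGeometry:
    """100-ml unbaffled paddle vessel: D=6.5 cm, d=D/2, H=0.46 D, b/D=0.06."""
    D = 0.065
    return VesselGeometry(
        vessel_diameter=D,
        impeller_diameter=D / 2,
        blade_height=0.06 * D,
        liquid_height=0.46 * D,
        working_volume=1.0e-4,
    )


@pytest.fixture
def water() -> FluidProperties:
    return FluidProperties.water()


@pytest.fixture
def rpm50() -> AgitationCondition:
    return AgitationCondition(50.0)


@pytest.fixture
def rpm100() -> AgitationCondition:
    return AgitationCondition(100.0)
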