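import pytest

from samp import (
    ActuatorModel,
    ChannelGeometry,
    FluidProperties,
    PumpConfig,
)

# The benchtop device: antisymmetric AR 3 / (1/3) pumping channels with
# equal cross-sections, 5 mm long, square 500 um observation channels.
HAR_CHANNEL = ChannelGeometry(width=200.0, height=600.0, length=5000.0)
LAR_CHANNEL = ChannelGeometry(width=600.0, height=200.0, length=5000.0)
OBS_CHANNEL = ChannelGeometry(width=500.0, height=500.0, length=10000.0)


@pytest.fixture
def fluid() -> FluidProperties:
    return FluidProperties()


@pytest.fixture
def continuous_pump() -> PumpConfig:
    """Antisymmetric pump without observation channels (continuous design)."""
    return PumpConfig(left=HAR_CHANNEL, right=LAR_CHANNEL)


@pytest.fixture
def observed_pump() -> PumpConfig:
    """Antisymmetric pump with identical observation channels on both sides."""
    return PumpConfig(
        left=HAR_CHANNEL,
        right=LAR_CHANNEL,
        left_observation=OBS_CHANNEL,
        right_observation=OBS_CHANNEL,
    )


@pytest.fixture
def symmetric_pump() -> PumpConfig:
    """Identical channels on both sides: no pumping by symmetry."""
    return PumpConfig(left=HAR_CHANNEL, right=HAR_CHANNEL)


@pytest.fixture
def actuator() -> ActuatorModel:
    return ActuatorModel()
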