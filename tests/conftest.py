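import math

import pytest

from nitracer import TrueParameters, VesselGeometry


@pytest.fixture
def microcosm() -> VesselGeometry:
    """Holobiont microcosm: 227 mL, 37 mg SFDW animal."""
    return VesselGeometry.microcosm(water_volume_l=0.227, biomass_sfdw_g=0.037)


@pytest.fixture
def core() -> VesselGeometry:
    """Sediment core: 0.8 L overlying water, 8.4 cm inner diameter."""
    return VesselGeometry.core(water_volume_l=0.8)


@pytest.fixture
def noiseless_params() -> TrueParameters:
    """Ground truth with zero measurement noise for exact-recovery tests."""
    return TrueParameters(noise_cv=0.0, seed=7)


@pytest.fixture
def core_area() -> float:
    return math.pi * 0.042**2
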