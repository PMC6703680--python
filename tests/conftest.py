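import numpy as np
import pytest

from shadegame.architecture import (AngleParams, Leaf, OrganSchedule, Plant,
                                    PlasticityStrategy)
from shadegame.light import LightSourceSpec, StandLayout
from shadegame.physiology import GrowthCurveParams, PhysiologyParams
from shadegame.simulate import StandConfiguration


@pytest.fixture
def phys():
    return PhysiologyParams()


@pytest.fixture
def growth():
    return GrowthCurveParams(w_max=10.0, t_e=20.0, t_m=10.0)


@pytest.fixture
def schedule():
    return OrganSchedule()


@pytest.fixture
def leaf():
    return Leaf(rank=1, emergence_day=4.5, azimuth=0.0,
                petiole_length=0.02, petiole_biomass=2.0,
                lamina_area=2e-4, lamina_biomass=5.0, elevation_angle=20.0)


@pytest.fixture
def plant():
    p = Plant(position=(0.0, 0.0), strategy=PlasticityStrategy(0.5))
    p.leaves = [
        Leaf(rank=1, emergence_day=4.5, azimuth=0.0, petiole_biomass=2.0,
             lamina_biomass=6.0, petiole_length=0.02, lamina_area=2e-4),
        Leaf(rank=2, emergence_day=6.0, azimuth=137.5, petiole_biomass=1.0,
             lamina_biomass=3.0, petiole_length=0.01, lamina_area=1e-4),
    ]
    p.root_biomass = 2.0
    return p


@pytest.fixture
def small_source():
    """Reduced ray budget for unit tests."""
    return LightSourceSpec(ray_count=900, sensor_up_rays=16,
                           sensor_down_rays=8)


@pytest.fixture
def tiny_stand():
    """Smallest legal stand, short run: fast simulator unit tests."""
    return StandConfiguration(
        density=400.0, resident_alpha=0.3, scenario_n=2.0, days=12,
        rows=3, cols=3, seed=11, source=LightSourceSpec(ray_count=500))
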