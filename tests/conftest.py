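import math

import numpy as np
import pytest
from hypothesis import settings

from leafecho.acoustics import FrequencyBand, SonarBeam
from leafecho.geometry import LeafDisc
from leafecho.lsystem import GeometryParams

settings.register_profile("ci", derandomize=True, max_examples=30)
settings.load_profile("ci")


@pytest.fixture
def band():
    return FrequencyBand()


@pytest.fixture
def beam():
    """40 deg symmetric beam at the origin looking along +x, z up."""
    return SonarBeam(
        position=np.zeros(3),
        boresight=np.array([1.0, 0.0, 0.0]),
        beamwidth_az=math.radians(40.0),
        beamwidth_el=math.radians(40.0),
    )


@pytest.fixture
def facing_disc():
    """One leaf disc on the boresight at 1 m, facing the sonar."""
    return LeafDisc(center=[1.0, 0.0, 0.0], radius=0.02, normal=[-1.0, 0.0, 0.0])


@pytest.fixture
def noiseless_params():
    """Turtle geometry with every random element switched off or degenerate."""
    return GeometryParams(
        ratio_noise_sd=0.0,
        angle_noise_sd=0.0,
        raise_fraction_range=(0.3, 0.3),
        azimuth_rule="golden-angle",
    )
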