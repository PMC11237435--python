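import numpy as np
import pytest

from iceclock import synth


@pytest.fixture
def uniform_field():
    field, strain = synth.make_velocity_field("uniform", 100.0)
    return field, strain


@pytest.fixture
def rotational_unit_field():
    """u = -y, v = x on a fine grid around the unit circle (m-scale units)."""
    x = np.linspace(-2.0, 2.0, 201)
    field, strain = synth.make_velocity_field("rotational", 1.0, grid=(x, x))
    return field, strain


@pytest.fixture
def constant_accretion_series():
    return synth.make_segments(
        synth.IceScenario(
            name="constant_accretion", accretion_rate=0.5, total_time=100.0, dt=1.0
        )
    )


@pytest.fixture
def steady_strain_series():
    return synth.make_segments(
        synth.IceScenario(
            name="steady_strain",
            accretion_rate=0.5,
            strain_rate=0.005,
            total_time=1000.0,
            dt=0.5,
        )
    )
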