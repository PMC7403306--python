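import numpy as np
import pytest

from lcr import (
    AmbientConditions,
    Material,
    simulate_cycle,
)

FIBRIN_R_MAX = 126e-6
FIBRIN_ETA = 20e3
FIBRIN_EPS = 0.25


@pytest.fixture(scope="session")
def ambient():
    return AmbientConditions()


@pytest.fixture(scope="session")
def fibrin_material():
    """Fitted 2.5 mg/mL fibrin at 12 uJ: eta = 20 kPa, eps_f_rr = 0.25."""
    return Material(elastic_modulus=FIBRIN_ETA, radial_failure_strain=FIBRIN_EPS)


@pytest.fixture(scope="session")
def fibrin_trajectory(fibrin_material, ambient):
    return simulate_cycle(FIBRIN_R_MAX, fibrin_material, ambient)


@pytest.fixture(scope="session")
def inviscid_water():
    """No elasticity, viscosity or surface tension: the Rayleigh limit."""
    return Material(
        elastic_modulus=0.0, kinematic_viscosity=0.0, surface_tension=0.0
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
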