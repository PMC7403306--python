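"""Closed-form constitutive relations for a cavitation bubble in a
Neo-Hookean viscoelastic medium with material failure.

The bubble of radius ``R_B`` sits in an incompressible Neo-Hookean solid
characterized by a single elastic modulus ``eta``.  The gas inside is
adiabatic with internal pressure equal to the vapor pressure at the
maximum radius, which fixes the equilibrium radius

    R_0 = R_max * (p_v / p_inf)**(1 / (3 * kappa)).

The elastic stress the surroundings exert on the bubble wall follows one
of three laws along the growth/collapse cycle:

* **intact** (path A): the Neo-Hookean stress
  ``E_L = (eta/2) * [5 - 4*(R_0/R_B) - (R_0/R_B)**4]``;
* **failed** (path B): once the radial wall strain reaches the failure
  strain, the stress plateaus at the constant ``E_f = E_L(R_f)``;
* **recovery** (path C): during collapse the stress is the rescaled law
  ``E_R = E_f * bracket(R_B) / bracket(R_max)``, continuous with path B
  at ``R_max``.

The wall strains are the Green-Lagrange finite strains evaluated at the
bubble wall; the radial component's sign is flipped so that compression
during expansion is positive:

    eps_rr = -1/2 * [(R_0/R_B)**4 - 1]        (bounded above by 1/2)
    eps_tt = +1/2 * [(R_B/R_0)**2 - 1]

Because ``eps_rr`` can never reach 1/2, a radial failure strain of 0.5
or more means the material never fails; that state is represented by
``Material.radial_failure_strain is None`` and by an infinite failure
radius, never by an exception.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

__all__ = [
    "Material",
    "AmbientConditions",
    "CycleGeometry",
    "WallStrains",
    "equilibrium_radius",
    "internal_pressure",
    "elastic_stress_intact",
    "failure_stress",
    "elastic_stress_recovery",
    "wall_strains",
    "failure_radius",
    "circumferential_failure_strain",
    "NO_FAILURE",
]

#: sentinel used in user-facing tables/configs for "material never fails"
NO_FAILURE: None = None


@dataclass(frozen=True)
class AmbientConditions:
    """Far-field and gas-phase constants.

    Parameters
    ----------
    far_field_pressure : float
        Isotropic pressure far from the bubble, Pa.  Default 101325 Pa.
    vapor_pressure : float
        Vapor pressure inside the bubble at the maximum radius, Pa.
        Default 3169 Pa (water at 25 degC).
    adiabatic_index : float
        Polytropic exponent kappa of the bubble gas.  Default 4/3.
    temperature : float
        Absolute temperature, K.  Default 298.15 K.
    """

    far_field_pressure: float = 101325.0
    vapor_pressure: float = 3169.0
    adiabatic_index: float = 4.0 / 3.0
    temperature: float = 298.15

    def __post_init__(self) -> None:
        if not 0.0 < self.vapor_pressure < self.far_field_pressure:
            raise ValueError("require 0 < vapor_pressure < far_field_pressure")
        if self.adiabatic_index <= 1.0:
            raise ValueError("adiabatic_index must exceed 1")
        if self.temperature <= 0.0:
            raise ValueError("temperature must be positive")


@dataclass(frozen=True)
class Material:
    """Mechanical constants of the medium surrounding the bubble.

    Parameters
    ----------
    elastic_modulus : float
        Neo-Hookean elastic modulus ``eta``, Pa.
    kinematic_viscosity : float
        ``nu``, m^2/s.  Default 1e-6 (water at 25 degC).
    density : float
        ``rho``, kg/m^3.  Default 997 (water at 25 degC).
    surface_tension : float
        ``S``, N/m.  Default 0.072 (water).
    radial_failure_strain : float or None
        Radial wall strain at which the material ruptures,
        dimensionless, in [0, 0.5).  ``None`` (or any value >= 0.5,
        which is normalized to ``None``) means the material never fails.
    """

    elastic_modulus: float = 0.0
    kinematic_viscosity: float = 1.0e-6
    density: float = 997.0
    surface_tension: float = 0.072
    radial_failure_strain: Optional[float] = None

    def __post_init__(self) -> None:
        if self.elastic_modulus < 0:
            raise ValueError("elastic_modulus must be >= 0")
        if self.kinematic_viscosity < 0:
            raise ValueError("kinematic_viscosity must be >= 0")
        if self.density <= 0:
            raise ValueError("density must be > 0")
        if self.surface_tension < 0:
            raise ValueError("surface_tension must be >= 0")
        eps = self.radial_failure_strain
        if eps is not None:
            if eps < 0:
                raise ValueError("radial_failure_strain must be >= 0")
            if eps >= 0.5:
                # radial wall strain is bounded above by 0.5: a nominal
                # failure strain >= 0.5 is unreachable == never fails
                object.__setattr__(self, "radial_failure_strain", None)

    @property
    def can_fail(self) -> bool:
        return self.radial_failure_strain is not None


@dataclass(frozen=True)
class CycleGeometry:
    """Radii that pin down one bubble cycle: R_max, R_0, and (when the
    material fails) the failure radius R_f."""

    max_radius: float
    equilibrium_radius: float
    failure_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if not 0 < self.equilibrium_radius < self.max_radius:
            raise ValueError("require 0 < R_0 < R_max")
        if self.failure_radius is not None and not (
            self.failure_radius >= self.equilibrium_radius
        ):
            raise ValueError("failure radius must be >= R_0 when present")


@dataclass(frozen=True)
class WallStrains:
    """Green-Lagrange strains at the bubble wall (radial sign flipped so
    compression during expansion is positive)."""

    radial: float
    circumferential: float


def equilibrium_radius(r_max: float, ambient: AmbientConditions = AmbientConditions()) -> float:
    """Equilibrium bubble radius ``R_0 = R_max (p_v/p_inf)**(1/(3 kappa))``.

    The cavity size at which the adiabatic gas pressure balances the
    far field, before any elastic stress is applied.
    """
    r_max = np.asarray(r_max, dtype=float)
    if np.any(r_max <= 0):
        raise ValueError("R_max must be positive")
    ratio = ambient.vapor_pressure / ambient.far_field_pressure
    out = r_max * ratio ** (1.0 / (3.0 * ambient.adiabatic_index))
    return float(out) if np.ndim(out) == 0 else out


def internal_pressure(
    r_b, r_max: float, ambient: AmbientConditions = AmbientConditions()
):
    """Adiabatic internal gas pressure ``p_B = p_v (R_max/R_B)**(3 kappa)``."""
    r_b = np.asarray(r_b, dtype=float)
    if np.any(r_b <= 0) or r_max <= 0:
        raise ValueError("radii must be positive")
    out = ambient.vapor_pressure * (r_max / r_b) ** (3.0 * ambient.adiabatic_index)
    return float(out) if np.ndim(out) == 0 else out


def _neo_hookean_bracket(x):
    """The bracket ``5 - 4 x - x**4`` with ``x = R_0 / R_B``."""
    return 5.0 - 4.0 * x - x**4


def elastic_stress_intact(r_b, r_0: float, eta: float):
    """Neo-Hookean elastic stress of the intact material (path A).

    Zero at ``R_B = R_0``, negative in compression (``R_B < R_0``), and
    saturating at ``5 eta / 2`` as ``R_B -> inf``.
    """
    r_b = np.asarray(r_b, dtype=float)
    if np.any(r_b <= 0):
        raise ValueError("R_B must be positive")
    out = 0.5 * eta * _neo_hookean_bracket(r_0 / r_b)
    return float(out) if np.ndim(out) == 0 else out


def failure_stress(r_f: float, r_0: float, eta: float) -> float:
    """Constant plateau stress after rupture (path B): the intact law
    frozen at the failure radius."""
    if r_f < r_0:
        raise ValueError("failure radius must be >= R_0")
    return elastic_stress_intact(r_f, r_0, eta)


def elastic_stress_recovery(r_b, r_0: float, r_max: float, e_f: float):
    """Elastic stress during collapse after failure (path C).

    Rescaled Neo-Hookean law, continuous with the plateau at
    ``R_B = R_max`` and vanishing at ``R_B = R_0``.
    """
    denom = _neo_hookean_bracket(r_0 / r_max)
    if denom == 0.0:
        raise ZeroDivisionError("degenerate geometry: R_max equals R_0")
    r_b = np.asarray(r_b, dtype=float)
    if np.any(r_b <= 0):
        raise ValueError("R_B must be positive")
    out = e_f * _neo_hookean_bracket(r_0 / r_b) / denom
    return float(out) if np.ndim(out) == 0 else out


def wall_strains(r_b: float, r_0: float) -> WallStrains:
    """Green-Lagrange strains at the bubble wall.

    ``radial = -1/2 [(R_0/R_B)**4 - 1]`` (compression positive, < 1/2),
    ``circumferential = 1/2 [(R_B/R_0)**2 - 1]``.
    """
    if r_b <= 0 or r_0 <= 0:
        raise ValueError("radii must be positive")
    x = r_0 / r_b
    return WallStrains(
        radial=-0.5 * (x**4 - 1.0),
        circumferential=0.5 * ((r_b / r_0) ** 2 - 1.0),
    )


def failure_radius(eps_f_rr: Optional[float], r_0: float) -> float:
    """Bubble radius at which the radial wall strain reaches ``eps_f_rr``.

    Inversion of the radial wall-strain law:
    ``R_f = R_0 (1 - 2 eps)**(-1/4)``.

    A failure strain of ``None`` or >= 0.5 is unreachable (the radial
    wall strain asymptotes to 0.5), signalled by returning ``inf``.
    """
    if eps_f_rr is None:
        return np.inf
    if eps_f_rr < 0:
        raise ValueError("radial failure strain must be >= 0")
    if eps_f_rr >= 0.5:
        return np.inf
    if r_0 <= 0:
        raise ValueError("R_0 must be positive")
    return r_0 * (1.0 - 2.0 * eps_f_rr) ** (-0.25)


def circumferential_failure_strain(eps_f_rr: float) -> float:
    """Circumferential failure strain implied by the radial one.

    Composition of the two wall-strain laws through the failure radius:
    ``eps_tt = 1/2 [(1 - 2 eps_rr)**(-1/2) - 1]``.
    """
    if eps_f_rr is None or eps_f_rr >= 0.5:
        return np.inf
    if eps_f_rr < 0:
        raise ValueError("radial failure strain must be >= 0")
    return 0.5 * ((1.0 - 2.0 * eps_f_rr) ** (-0.5) - 1.0)


def cycle_geometry(
    r_max: float,
    material: Material,
    ambient: AmbientConditions = AmbientConditions(),
) -> CycleGeometry:
    """Assemble the cycle geometry (R_max, R_0, R_f) for a material.

    ``failure_radius`` is present only when the material can fail *and*
    the bubble actually reaches it (``R_f < R_max``).
    """
    r_0 = equilibrium_radius(r_max, ambient)
    r_f = failure_radius(material.radial_failure_strain, r_0)
    return CycleGeometry(
        max_radius=r_max,
        equilibrium_radius=r_0,
        failure_radius=r_f if r_f < r_max else None,
    )
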