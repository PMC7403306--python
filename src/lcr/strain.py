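"""Finite-strain fields around the bubble, strain rates, and the
polymer mesh-size estimate.

The surroundings are incompressible and spherically symmetric (the same
kinematics underlying the governing bubble equation), so a material
point at reference radius ``r_ref`` (measured in the undeformed
configuration, ``r_ref >= R_0``) moves to

    r(r_ref) = (r_ref**3 + R_B**3 - R_0**3)**(1/3)

and carries the Green-Lagrange strains

    eps_rr = -1/2 [(r_ref/r)**4 - 1]     (compression positive)
    eps_tt = +1/2 [(r/r_ref)**2 - 1]

which reduce to the wall strains at ``r_ref = R_0``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.constants import Boltzmann

from .constitutive import AmbientConditions, equilibrium_radius
from .dynamics import Trajectory

__all__ = [
    "StrainField",
    "MeshEstimate",
    "deformed_radius",
    "strain_field",
    "strain_rate_estimate",
    "circumferential_strain_series",
    "mesh_size",
]


@dataclass
class StrainField:
    """Strain field sampled on a reference grid (units of R_0)."""

    reference_positions: np.ndarray  # r_ref / R_0
    deformed_positions: np.ndarray  # r, m
    radial_strain: np.ndarray
    circumferential_strain: np.ndarray
    evaluated_at: float  # R_B, m
    max_radius: float
    equilibrium_radius: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "r_ref_over_R0": self.reference_positions,
                "radius_deformed_um": self.deformed_positions * 1e6,
                "strain_rr": self.radial_strain,
                "strain_tt": self.circumferential_strain,
            }
        )

    def extent_above(self, threshold: float) -> float:
        """Largest reference position (units of R_0) whose
        circumferential strain still exceeds ``threshold``."""
        above = self.reference_positions[self.circumferential_strain > threshold]
        return float(above.max()) if above.size else 0.0


@dataclass(frozen=True)
class MeshEstimate:
    storage_modulus: float  # Pa
    temperature: float  # K
    mesh_size_m: float


def deformed_radius(r_ref, r_b: float, r_0: float):
    """Deformed position of a material point (volume conservation of
    the incompressible surroundings)."""
    r_ref = np.asarray(r_ref, dtype=float)
    if np.any(r_ref < r_0):
        raise ValueError("r_ref < R_0 lies inside the cavity")
    out = (r_ref**3 + r_b**3 - r_0**3) ** (1.0 / 3.0)
    return float(out) if np.ndim(out) == 0 else out


def strain_field(
    r_max: float,
    ambient: AmbientConditions = AmbientConditions(),
    grid=None,
    r_b: float | None = None,
) -> StrainField:
    """Green-Lagrange strain field in the surroundings.

    Evaluated by default at full expansion (``R_B = R_max``), on a grid
    of reference positions in units of R_0 (default: 400 log-spaced
    points from the wall to 10 R_0).
    """
    r_0 = equilibrium_radius(r_max, ambient)
    if r_b is None:
        r_b = r_max
    if grid is None:
        grid = np.geomspace(1.0, 10.0, 400)
    grid = np.asarray(grid, dtype=float)
    if np.any(grid < 1.0):
        raise ValueError("grid positions are in units of R_0 and must be >= 1")
    r_ref = grid * r_0
    r = deformed_radius(r_ref, r_b, r_0)
    return StrainField(
        reference_positions=grid,
        deformed_positions=r,
        radial_strain=-0.5 * ((r_ref / r) ** 4 - 1.0),
        circumferential_strain=0.5 * ((r / r_ref) ** 2 - 1.0),
        evaluated_at=r_b,
        max_radius=r_max,
        equilibrium_radius=r_0,
    )


def circumferential_strain_series(trajectory: Trajectory):
    """Wall circumferential strain and its instantaneous rate along a
    simulated cycle.  Returns ``(t, eps_tt, deps_tt_dt)``."""
    r_0 = trajectory.geometry.equilibrium_radius
    eps = 0.5 * ((trajectory.radii / r_0) ** 2 - 1.0)
    rate = trajectory.radii * trajectory.velocities / r_0**2
    return trajectory.times, eps, rate


def strain_rate_estimate(trajectory: Trajectory) -> float:
    """Characteristic strain rate: peak wall circumferential strain
    divided by the time from cycle start to the apex, 1/s."""
    if len(trajectory.times) < 2:
        raise ValueError("trajectory too short for a rate estimate")
    r_0 = trajectory.geometry.equilibrium_radius
    eps_max = 0.5 * ((trajectory.radii.max() / r_0) ** 2 - 1.0)
    rise = trajectory.apex_time - trajectory.times[0]
    if rise <= 0:
        raise ValueError("degenerate trajectory: no growth phase")
    return eps_max / rise


def mesh_size(storage_modulus: float, temperature: float = 298.15) -> MeshEstimate:
    """Characteristic polymer network pore scale
    ``delta = (k_B T / G')**(1/3)``.

    Used to confirm the continuum treatment: the ~100 µm region the
    bubble engages is orders of magnitude above the nm-scale mesh.
    """
    if storage_modulus <= 0 or temperature <= 0:
        raise ValueError("G' and T must be positive")
    delta = (Boltzmann * temperature / storage_modulus) ** (1.0 / 3.0)
    return MeshEstimate(
        storage_modulus=storage_modulus,
        temperature=temperature,
        mesh_size_m=delta,
    )
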