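"""Bubble-dynamics integration through one growth/collapse cycle.

The governing equation (a Rayleigh-Plesset equation extended with a
Neo-Hookean elastic stress ``E``) is

    R Rdd + 3/2 Rd^2 = (p_B - p_inf)/rho - 2 S/(rho R) - 4 nu Rd / R - E/rho

with the elastic stress switching between the intact, failed and
recovery laws of :mod:`lcr.constitutive` over the cycle:

* growth below the failure radius: intact law (phase A);
* growth between ``R_f`` and ``R_max``: constant plateau (phase B);
* collapse: recovery law (phase C).

The model pins down exactly one state, the apex ``(R_max, Rd = 0)``,
because ``R_max`` both parameterizes the gas law and is the fitted
quantity.  We therefore integrate the growth half *backward in time*
from the apex and the collapse half forward from it, stopping each half
at the velocity turning point where the adiabatic gas term (plus, at
small radii, Neo-Hookean compression) arrests the wall.  The cycle time
``T_hg`` is the time between the two turning points.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .constitutive import (
    AmbientConditions,
    CycleGeometry,
    Material,
    cycle_geometry,
    elastic_stress_intact,
    elastic_stress_recovery,
    failure_stress,
    internal_pressure,
    wall_strains,
)

__all__ = [
    "Phase",
    "BubbleState",
    "Trajectory",
    "SolverError",
    "acceleration",
    "simulate_cycle",
    "water_cycle_time_analytic",
    "cycle_time_ratio",
    "sensitivity_map",
    "RAYLEIGH_FACTOR",
]

#: Rayleigh's collapse-time prefactor: t_c = 0.915 R sqrt(rho / dp)
RAYLEIGH_FACTOR = 0.915


class Phase(enum.Enum):
    """Constitutive phase of the material along the cycle."""

    ELASTIC_GROWTH = "A"
    PLASTIC_GROWTH = "B"
    RECOVERY = "C"
    NEWTONIAN = "N"
    ELASTIC_NO_FAILURE = "E"


class SolverError(RuntimeError):
    """Integration failed to locate a turning point."""


@dataclass(frozen=True)
class BubbleState:
    time: float
    radius: float
    velocity: float


@dataclass
class Trajectory:
    """Simulated bubble history over one full cycle.

    ``t = 0`` at the growth-side turning point (inception); the apex sits
    at ``t = growth_time`` and the cycle ends at ``t = cycle_time``.
    """

    times: np.ndarray
    radii: np.ndarray
    velocities: np.ndarray
    phases: np.ndarray  # Phase value codes, one per sample
    geometry: CycleGeometry
    material: Material
    ambient: AmbientConditions
    growth_time: float
    collapse_time: float
    failed: bool
    mode: str

    @property
    def cycle_time(self) -> float:
        """Full growth/collapse cycle duration T_hg, s."""
        return self.growth_time + self.collapse_time

    @property
    def apex_time(self) -> float:
        return self.growth_time

    def radius_at(self, t) -> np.ndarray:
        """Model radius at arbitrary times within the cycle (linear
        interpolation of the densely sampled solution)."""
        return np.interp(np.asarray(t, dtype=float), self.times, self.radii)

    def states(self) -> Sequence[BubbleState]:
        return [
            BubbleState(t, r, v)
            for t, r, v in zip(self.times, self.radii, self.velocities)
        ]

    def to_frame(self) -> pd.DataFrame:
        """Trajectory as a table in boundary units (µs, µm)."""
        return pd.DataFrame(
            {
                "time_us": self.times * 1e6,
                "radius_um": self.radii * 1e6,
                "velocity_m_per_s": self.velocities,
                "phase": self.phases,
            }
        )


def _elastic_stress(
    r: float,
    phase: Phase,
    material: Material,
    geometry: CycleGeometry,
) -> float:
    """Elastic stress E for the given phase at radius r."""
    r0 = geometry.equilibrium_radius
    if phase is Phase.NEWTONIAN:
        return 0.0
    if phase in (Phase.ELASTIC_GROWTH, Phase.ELASTIC_NO_FAILURE):
        return elastic_stress_intact(r, r0, material.elastic_modulus)
    if phase is Phase.PLASTIC_GROWTH:
        return failure_stress(geometry.failure_radius, r0, material.elastic_modulus)
    if phase is Phase.RECOVERY:
        if geometry.failure_radius is None:
            # never failed: recovery is just the intact law
            return elastic_stress_intact(r, r0, material.elastic_modulus)
        e_f = failure_stress(geometry.failure_radius, r0, material.elastic_modulus)
        return elastic_stress_recovery(r, r0, geometry.max_radius, e_f)
    raise ValueError(f"unknown phase {phase}")


def acceleration(
    state: BubbleState,
    phase: Phase,
    material: Material,
    ambient: AmbientConditions,
    geometry: CycleGeometry,
) -> float:
    """Radial wall acceleration d2R/dt2 from the governing equation."""
    r, v = state.radius, state.velocity
    if r <= 0:
        raise ValueError("bubble radius must be positive")
    rho = material.density
    p_b = internal_pressure(r, geometry.max_radius, ambient)
    e = _elastic_stress(r, phase, material, geometry)
    return (
        (p_b - ambient.far_field_pressure) / rho
        - 2.0 * material.surface_tension / (rho * r)
        - 4.0 * material.kinematic_viscosity * v / r
        - e / rho
        - 1.5 * v * v
    ) / r


def _make_rhs(
    phase: Phase,
    material: Material,
    ambient: AmbientConditions,
    geometry: CycleGeometry,
    time_sign: float,
) -> Callable:
    """RHS of the first-order system in integration time tau.

    ``time_sign = +1`` integrates physical time forward, ``-1`` backward
    (the radius acceleration is invariant under time reversal; only the
    viscous term, odd in Rdot, changes sign).
    """
    rho = material.density
    p_v = ambient.vapor_pressure
    p_inf = ambient.far_field_pressure
    three_kappa = 3.0 * ambient.adiabatic_index
    s = material.surface_tension
    nu = material.kinematic_viscosity
    r_max = geometry.max_radius

    def rhs(_tau, y):
        r, v = y
        p_b = p_v * (r_max / r) ** three_kappa
        e = _elastic_stress(r, phase, material, geometry)
        acc = (
            (p_b - p_inf) / rho
            - 2.0 * s / (rho * r)
            - 4.0 * nu * (time_sign * v) / r
            - e / rho
            - 1.5 * v * v
        ) / r
        return (v, acc)

    return rhs


@dataclass
class _Segment:
    tau: np.ndarray  # integration-time samples (increasing)
    r: np.ndarray
    v: np.ndarray
    phase: Phase


def _integrate_half(
    segments_plan: list[tuple[Phase, Optional[float]]],
    geometry: CycleGeometry,
    material: Material,
    ambient: AmbientConditions,
    time_sign: float,
    rtol: float,
    max_step: float,
    t_limit: float,
    samples_per_segment: int,
) -> tuple[list[_Segment], float]:
    """Integrate from the apex until the velocity turning point.

    ``segments_plan`` is an ordered list of (phase, stop_radius); a
    segment ends when R drops below stop_radius (None = run to the
    turning point).  Returns the sampled segments (in integration time)
    and the half-duration.
    """
    # Analytic nudge off the apex: at (R_max, 0) the velocity event is
    # identically zero, so take one tiny second-order Taylor step.
    a0 = acceleration(
        BubbleState(0.0, geometry.max_radius, 0.0),
        segments_plan[0][0],
        material,
        ambient,
        geometry,
    )
    if a0 >= 0.0:
        raise SolverError(
            "no inward acceleration at the apex; is R_max <= R_0 or the "
            "elastic stress negative there?"
        )
    dt0 = 1e-7 * t_limit
    r = geometry.max_radius + 0.5 * a0 * dt0 * dt0
    v = a0 * dt0
    tau = dt0

    segments: list[_Segment] = []
    atol = [1e-12, 1e-6]  # m, m/s — radii are ~1e-4 m, speeds up to ~1e2 m/s
    for phase, stop_radius in segments_plan:
        events = []

        def turning(_t, y):
            return y[1]

        turning.terminal = True
        turning.direction = 1.0
        events.append(turning)
        if stop_radius is not None:
            def crossing(_t, y, _sr=stop_radius):
                return y[0] - _sr

            crossing.terminal = True
            crossing.direction = -1.0
            events.append(crossing)

        sol = solve_ivp(
            _make_rhs(phase, material, ambient, geometry, time_sign),
            (tau, tau + t_limit),
            (r, v),
            method="LSODA",
            events=events,
            dense_output=True,
            rtol=rtol,
            atol=atol,
            max_step=max_step,
        )
        if not sol.success:
            raise SolverError(f"integration failed in phase {phase}: {sol.message}")
        hit_turning = len(sol.t_events[0]) > 0
        hit_crossing = stop_radius is not None and len(sol.t_events[1]) > 0
        if not hit_turning and not hit_crossing:
            raise SolverError(
                f"no turning point found within {t_limit:.3e} s in phase "
                f"{phase} (R_max={geometry.max_radius:.3e} m, "
                f"eta={material.elastic_modulus:.3e} Pa)"
            )
        tau_end = sol.t[-1]
        ts = np.linspace(tau, tau_end, samples_per_segment)
        ys = sol.sol(ts)
        segments.append(_Segment(tau=ts, r=ys[0], v=ys[1], phase=phase))
        r, v = ys[0][-1], ys[1][-1]
        tau = tau_end
        if hit_turning:
            break
    return segments, tau


def simulate_cycle(
    r_max: float,
    material: Material,
    ambient: AmbientConditions = AmbientConditions(),
    mode: str = "failure",
    rtol: float = 1e-9,
    max_step: Optional[float] = None,
    samples_per_segment: int = 400,
) -> Trajectory:
    """Simulate one full growth/collapse cycle.

    Parameters
    ----------
    r_max : float
        Maximum bubble radius, m.  Must exceed the equilibrium radius.
    material, ambient :
        Physical constants.  ``material.radial_failure_strain`` controls
        whether and where the failure plateau engages.
    mode : {"failure", "elastic", "newtonian"}
        "failure" applies the A/B/C switching law (degrading gracefully
        to the intact law when the failure radius is never reached);
        "elastic" ignores failure entirely; "newtonian" zeroes the
        elastic stress.
    rtol : float
        Relative tolerance of the adaptive (LSODA) integrator.
    max_step : float, optional
        Cap on the solver step, s.  Default: 1/50 of the water-limit
        cycle time, small enough that phase-switch and turning events
        cannot be stepped over.
    samples_per_segment : int
        Number of equally spaced samples stored per integration segment.

    Returns
    -------
    Trajectory
        With ``t = 0`` at the growth-side turning point.
    """
    if mode not in ("failure", "elastic", "newtonian"):
        raise ValueError(f"unknown mode {mode!r}")
    geometry = cycle_geometry(r_max, material, ambient)
    if mode != "failure":
        geometry = CycleGeometry(
            max_radius=geometry.max_radius,
            equilibrium_radius=geometry.equilibrium_radius,
            failure_radius=None,
        )
    failed = geometry.failure_radius is not None

    t_water = water_cycle_time_analytic(r_max, material.density, ambient)
    t_limit = 3.0 * t_water
    if max_step is None:
        max_step = t_water / 50.0

    if mode == "newtonian":
        growth_plan = [(Phase.NEWTONIAN, None)]
        collapse_plan = [(Phase.NEWTONIAN, None)]
    elif mode == "elastic" or not failed:
        label = Phase.ELASTIC_NO_FAILURE
        growth_plan = [(label, None)]
        collapse_plan = [(label, None)]
    else:
        # reversed-time growth: plateau B from the apex down to R_f,
        # then intact law A to the inception turning point
        growth_plan = [
            (Phase.PLASTIC_GROWTH, geometry.failure_radius),
            (Phase.ELASTIC_GROWTH, None),
        ]
        collapse_plan = [(Phase.RECOVERY, None)]

    growth_segments, t_growth = _integrate_half(
        growth_plan, geometry, material, ambient, -1.0,
        rtol, max_step, t_limit, samples_per_segment,
    )
    collapse_segments, t_collapse = _integrate_half(
        collapse_plan, geometry, material, ambient, +1.0,
        rtol, max_step, t_limit, samples_per_segment,
    )

    times: list[np.ndarray] = []
    radii: list[np.ndarray] = []
    vels: list[np.ndarray] = []
    phases: list[np.ndarray] = []
    # growth half: tau is time-before-apex, physical t = t_growth - tau;
    # physical velocity flips sign
    for seg in growth_segments:
        times.append(t_growth - seg.tau[::-1])
        radii.append(seg.r[::-1])
        vels.append(-seg.v[::-1])
        phases.append(np.full(seg.tau.shape, seg.phase.value))
    for seg in collapse_segments:
        times.append(t_growth + seg.tau)
        radii.append(seg.r)
        vels.append(seg.v)
        phases.append(np.full(seg.tau.shape, seg.phase.value))

    t = np.concatenate(times)
    order = np.argsort(t, kind="stable")
    # segment boundaries are sampled by both neighbours; keep one copy
    keep = np.concatenate(([True], np.diff(t[order]) > 0))
    order = order[keep]
    return Trajectory(
        times=t[order],
        radii=np.concatenate(radii)[order],
        velocities=np.concatenate(vels)[order],
        phases=np.concatenate(phases)[order],
        geometry=geometry,
        material=material,
        ambient=ambient,
        growth_time=t_growth,
        collapse_time=t_collapse,
        failed=failed,
        mode=mode,
    )


def water_cycle_time_analytic(
    r_max: float,
    density: float = 997.0,
    ambient: AmbientConditions = AmbientConditions(),
) -> float:
    """Cycle time of an identical bubble in an inviscid, tension-free,
    non-elastic liquid: twice the Rayleigh collapse time,

        T_w = 2 * 0.915 * R_max * sqrt(rho / (p_inf - p_v)).
    """
    if r_max < 0:
        raise ValueError("R_max must be non-negative")
    dp = ambient.far_field_pressure - ambient.vapor_pressure
    return 2.0 * RAYLEIGH_FACTOR * r_max * np.sqrt(density / dp)


def cycle_time_ratio(trajectory: Trajectory) -> float:
    """Shortening ratio T_hg / T_w of a simulated cycle relative to the
    water limit for the same maximum radius."""
    t_w = water_cycle_time_analytic(
        trajectory.geometry.max_radius, trajectory.material.density, trajectory.ambient
    )
    return trajectory.cycle_time / t_w


def sensitivity_map(
    r_max: float,
    eta_grid: Sequence[float],
    eps_f_grid: Sequence[Optional[float]],
    material_base: Material = Material(),
    ambient: AmbientConditions = AmbientConditions(),
    rtol: float = 1e-8,
) -> pd.DataFrame:
    """Cycle-shortening map over a grid of elastic modulus and radial
    failure strain at fixed maximum radius.

    Returns a table with columns ``eta_pa``, ``eps_f_rr``,
    ``cycle_time_us`` and ``ratio`` (= T_hg / T_w), one simulated cycle
    per grid point.
    """
    if len(eta_grid) == 0 or len(eps_f_grid) == 0:
        raise ValueError("grids must be non-empty")
    rows = []
    for eta in eta_grid:
        for eps in eps_f_grid:
            material = Material(
                elastic_modulus=eta,
                kinematic_viscosity=material_base.kinematic_viscosity,
                density=material_base.density,
                surface_tension=material_base.surface_tension,
                radial_failure_strain=eps,
            )
            try:
                traj = simulate_cycle(r_max, material, ambient, rtol=rtol)
            except SolverError as err:
                raise SolverError(
                    f"sensitivity map failed at eta={eta}, eps_f_rr={eps}: {err}"
                ) from err
            rows.append(
                {
                    "eta_pa": eta,
                    "eps_f_rr": np.nan if eps is None else eps,
                    "cycle_time_us": traj.cycle_time * 1e6,
                    "ratio": cycle_time_ratio(traj),
                }
            )
    return pd.DataFrame(rows)
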