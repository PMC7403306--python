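"""Cycle integration: Rayleigh limit, time-reversal symmetry, phase
switching, and agreement with an independent fixed-step RK4 oracle."""

import numpy as np
import pytest

from lcr import (
    AmbientConditions,
    Material,
    Phase,
    cycle_time_ratio,
    equilibrium_radius,
    failure_radius,
    failure_stress,
    elastic_stress_intact,
    elastic_stress_recovery,
    simulate_cycle,
    water_cycle_time_analytic,
)
from lcr.dynamics import BubbleState, acceleration, sensitivity_map


class TestAcceleration:
    def test_equilibrium_is_a_fixed_point_without_tension(self, ambient):
        mat = Material(elastic_modulus=20e3, surface_tension=0.0)
        geo = _geometry(120e-6, mat, ambient)
        a = acceleration(
            BubbleState(0.0, geo.equilibrium_radius, 0.0),
            Phase.ELASTIC_GROWTH, mat, ambient, geo,
        )
        assert a == pytest.approx(0.0, abs=1e-6)

    def test_apex_acceleration_inward_single_term(self, ambient):
        mat = Material(0.0, 0.0, 997.0, 0.0)
        geo = _geometry(120e-6, mat, ambient)
        a = acceleration(BubbleState(0.0, 120e-6, 0.0), Phase.NEWTONIAN, mat, ambient, geo)
        expected = (3169.0 - 101325.0) / (997.0 * 120e-6)
        assert a == pytest.approx(expected, rel=1e-12)
        assert a < 0

    def test_zero_modulus_elastic_equals_newtonian(self, ambient):
        mat = Material(elastic_modulus=0.0)
        geo = _geometry(100e-6, mat, ambient)
        st = BubbleState(0.0, 70e-6, 12.0)
        a_el = acceleration(st, Phase.ELASTIC_GROWTH, mat, ambient, geo)
        a_nw = acceleration(st, Phase.NEWTONIAN, mat, ambient, geo)
        assert a_el == a_nw


def _geometry(r_max, material, ambient):
    from lcr.constitutive import cycle_geometry

    return cycle_geometry(r_max, material, ambient)


class TestCycleBasics:
    def test_rayleigh_limit(self, inviscid_water, ambient):
        traj = simulate_cycle(120e-6, inviscid_water, ambient, mode="newtonian")
        assert cycle_time_ratio(traj) == pytest.approx(1.0, abs=0.02)

    def test_growth_collapse_mirror_symmetry(self, ambient):
        # nu = 0, S = 0: the governing equation is time-reversal
        # symmetric, so the no-failure halves must be mirror images
        mat = Material(20e3, 0.0, 997.0, 0.0, None)
        traj = simulate_cycle(110e-6, mat, ambient, mode="elastic")
        assert traj.growth_time == pytest.approx(traj.collapse_time, rel=1e-6)

    def test_peak_radius_matches_parameter(self, fibrin_trajectory):
        assert fibrin_trajectory.radii.max() == pytest.approx(126e-6, rel=1e-3)

    def test_time_strictly_increasing_and_unimodal(self, fibrin_trajectory):
        t, r = fibrin_trajectory.times, fibrin_trajectory.radii
        assert np.all(np.diff(t) >= 0)
        apex = np.argmax(r)
        assert np.all(np.diff(r[: apex + 1]) >= -1e-12)
        assert np.all(np.diff(r[apex:]) <= 1e-12)

    def test_domain_error_nonpositive_radius(self, ambient):
        with pytest.raises(ValueError):
            simulate_cycle(-1e-6, Material(elastic_modulus=1e3), ambient)

    def test_export_schema(self, fibrin_trajectory):
        frame = fibrin_trajectory.to_frame()
        assert list(frame.columns) == [
            "time_us", "radius_um", "velocity_m_per_s", "phase",
        ]
        assert len(frame) == len(fibrin_trajectory.times)


class TestPhaseSwitching:
    def test_phase_ordering_a_b_c(self, fibrin_trajectory):
        traj = fibrin_trajectory
        assert traj.failed
        codes = traj.phases
        t_a = traj.times[codes == "A"]
        t_b = traj.times[codes == "B"]
        t_c = traj.times[codes == "C"]
        assert len(t_a) and len(t_b) and len(t_c)
        assert t_a.max() <= t_b.min() + 1e-12
        assert t_b.max() <= t_c.min() + 1e-12
        # A and B only during growth
        assert t_b.max() <= traj.apex_time + 1e-12

    def test_stress_continuous_at_phase_boundaries(self, fibrin_trajectory):
        geo = fibrin_trajectory.geometry
        eta = fibrin_trajectory.material.elastic_modulus
        e_f = failure_stress(geo.failure_radius, geo.equilibrium_radius, eta)
        # A meets B at R_f
        assert elastic_stress_intact(
            geo.failure_radius, geo.equilibrium_radius, eta
        ) == pytest.approx(e_f, rel=1e-12)
        # B meets C at R_max
        assert elastic_stress_recovery(
            geo.max_radius, geo.equilibrium_radius, geo.max_radius, e_f
        ) == pytest.approx(e_f, rel=1e-12)

    def test_unreachable_failure_strain_equals_elastic_mode(self, ambient):
        mat = Material(elastic_modulus=15e3, radial_failure_strain=0.49)
        geo_rf = failure_radius(0.49, equilibrium_radius(100e-6, ambient))
        assert geo_rf > 100e-6  # strain never reached in this cycle
        t_fail = simulate_cycle(100e-6, mat, ambient, mode="failure")
        t_el = simulate_cycle(100e-6, mat, ambient, mode="elastic")
        assert not t_fail.failed
        assert t_fail.cycle_time == pytest.approx(t_el.cycle_time, rel=1e-9)

    def test_zero_failure_strain_has_inviscid_collapse(self, ambient):
        # eps_f_rr = 0 zeroes the elastic stress for all R >= R_0
        # (plateau and recovery laws carry E_f = 0), so the collapse
        # half must match the eta = 0 collapse; the inception segment
        # below R_0 still feels Neo-Hookean compression and may differ.
        mat = Material(20e3, 0.0, 997.0, 0.0, 0.0)
        ref = Material(0.0, 0.0, 997.0, 0.0, None)
        t_fail = simulate_cycle(100e-6, mat, ambient, mode="failure")
        t_zero = simulate_cycle(100e-6, ref, ambient, mode="elastic")
        assert t_fail.collapse_time == pytest.approx(t_zero.collapse_time, rel=1e-6)
        # growth above R_0 takes the same time in both (interpolate the
        # R_0 crossing to avoid sampling-resolution error)
        r0 = t_fail.geometry.equilibrium_radius
        durations = []
        for traj in (t_fail, t_zero):
            grow = traj.times <= traj.apex_time
            t_cross = np.interp(r0, traj.radii[grow], traj.times[grow])
            durations.append(traj.apex_time - t_cross)
        assert durations[0] == pytest.approx(durations[1], rel=1e-4)


class TestWaterCycleTime:
    @pytest.mark.parametrize(
        "r_max_um, expected_us", [(124.0, 22.9), (68.0, 12.6), (0.0, 0.0)]
    )
    def test_reference_values(self, r_max_um, expected_us, ambient):
        t = water_cycle_time_analytic(r_max_um * 1e-6, 997.0, ambient)
        assert t * 1e6 == pytest.approx(expected_us, abs=0.1)

    def test_ratio_monotone_in_modulus(self, ambient):
        r_lo = cycle_time_ratio(
            simulate_cycle(120e-6, Material(10e3, radial_failure_strain=0.5), ambient)
        )
        r_hi = cycle_time_ratio(
            simulate_cycle(120e-6, Material(40e3, radial_failure_strain=0.5), ambient)
        )
        assert r_hi < r_lo


class TestRK4Oracle:
    """Cross-check against an independent fixed-step classic RK4
    integration of the governing equation in physical time."""

    @staticmethod
    def _rhs(t, y, material, ambient, geometry, law):
        r, v = y
        rho = material.density
        p_b = ambient.vapor_pressure * (geometry.max_radius / r) ** (
            3.0 * ambient.adiabatic_index
        )
        acc = (
            (p_b - ambient.far_field_pressure) / rho
            - 2.0 * material.surface_tension / (rho * r)
            - 4.0 * material.kinematic_viscosity * v / r
            - law(r) / rho
            - 1.5 * v * v
        ) / r
        return np.array([v, acc])

    def _half_duration(self, material, ambient, geometry, laws, h):
        """RK4 from the apex (h < 0 for growth), linear-interp the
        velocity turning point."""
        y = np.array([geometry.max_radius, 0.0])
        # Taylor nudge off the apex, mirroring no law discontinuity
        f0 = self._rhs(0.0, y, material, ambient, geometry, laws(y[0]))
        y = y + h * f0 + 0.5 * h * h * np.array([f0[1], 0.0])
        t = h
        for _ in range(400000):
            law = laws(y[0])
            k1 = self._rhs(t, y, material, ambient, geometry, law)
            k2 = self._rhs(t, y + 0.5 * h * k1, material, ambient, geometry, law)
            k3 = self._rhs(t, y + 0.5 * h * k2, material, ambient, geometry, law)
            k4 = self._rhs(t, y + h * k3, material, ambient, geometry, law)
            y_new = y + h / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)
            t_new = t + h
            sign_flip = (y[1] * np.sign(h) < 0) and (y_new[1] * np.sign(h) >= 0)
            if sign_flip:
                frac = y[1] / (y[1] - y_new[1])
                return abs(t + frac * h)
            y, t = y_new, t_new
        raise AssertionError("RK4 oracle found no turning point")

    @pytest.mark.parametrize("seed", range(5))
    def test_cycle_time_agreement(self, seed, ambient):
        rng = np.random.default_rng(seed)
        r_max = rng.uniform(70e-6, 150e-6)
        eta = rng.uniform(0.0, 40e3)
        eps = rng.uniform(0.05, 0.45)
        material = Material(eta, 1e-6, 997.0, 0.072, eps)
        traj = simulate_cycle(r_max, material, ambient, mode="failure")
        geo = traj.geometry
        r0 = geo.equilibrium_radius

        if geo.failure_radius is not None:
            e_f = failure_stress(geo.failure_radius, r0, eta)

            def growth_laws(r):
                if r >= geo.failure_radius:
                    return lambda _r: e_f
                return lambda _r: elastic_stress_intact(_r, r0, eta)

            def collapse_laws(_r):
                return lambda _r: elastic_stress_recovery(_r, r0, geo.max_radius, e_f)
        else:
            def growth_laws(_r):
                return lambda _r: elastic_stress_intact(_r, r0, eta)

            collapse_laws = growth_laws

        # a negative step traverses the exact same solution backward,
        # so the growth half needs no change to the physical rhs
        h = water_cycle_time_analytic(r_max, 997.0, ambient) / 40000.0
        t_growth = self._half_duration(material, ambient, geo, growth_laws, -h)
        t_collapse = self._half_duration(material, ambient, geo, collapse_laws, h)
        assert t_growth + t_collapse == pytest.approx(traj.cycle_time, rel=1e-3)


class TestSensitivityMap:
    def test_small_map_monotonicity(self, ambient):
        m = sensitivity_map(
            120e-6, [0.0, 20e3], [0.2, 0.4], ambient=ambient, rtol=1e-8
        )
        piv = m.pivot(index="eta_pa", columns="eps_f_rr", values="ratio")
        arr = piv.to_numpy()
        assert arr[1, 0] < arr[0, 0]  # eta shortens
        assert arr[1, 1] < arr[1, 0]  # failure strain shortens
        assert np.allclose(arr[0], arr[0, 0], rtol=1e-6)  # eta=0 row flat

    def test_empty_grid_rejected(self, ambient):
        with pytest.raises(ValueError):
            sensitivity_map(120e-6, [], [0.2], ambient=ambient)
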