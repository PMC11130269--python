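"""Mechanistic-core unit and oracle tests.

Every closed-form expectation here is derived independently of the
implementation: matrix exponentials for the linear PK block, algebraic
steady states for the competitive binding kinetics, mass-balance integrals
for the absorption chain.
"""

import numpy as np
import pytest
from scipy.integrate import solve_ivp
from scipy.linalg import expm

from naloxsim import (
    DosingScenario,
    LigandBindingParams,
    SimConfig,
    SystemState,
    binding_rhs,
    biophase_rhs,
    equilibrium_occupancy,
    minute_ventilation,
    naloxone_pk_rhs,
    opioid_pk_rhs,
    simulate_subject,
)

OP = LigandBindingParams(k_on=2e-5, k_off=2e-3, n=1.0)
NX = LigandBindingParams(k_on=2e-4, k_off=3e-2, n=1.0)


class TestBindingRHS:
    def test_no_ligand_no_binding(self):
        assert binding_rhs(SystemState(), OP, NX) == (0.0, 0.0)

    def test_single_ligand_equilibrium_is_stationary(self):
        l_op = 500.0
        a = OP.k_on * l_op ** OP.n / OP.k_off
        r_eq = a / (1 + a)
        dr_op, dr_nx = binding_rhs(SystemState(l_op=l_op, r_op=r_eq), OP, NX)
        assert dr_op == pytest.approx(0.0, abs=1e-15)
        assert dr_nx == 0.0

    def test_saturated_receptors_can_only_unbind(self):
        state = SystemState(l_op=100.0, l_nx=100.0, r_op=0.6, r_nx=0.4)
        dr_op, dr_nx = binding_rhs(state, OP, NX)
        assert dr_op <= 0 and dr_nx <= 0

    def test_negative_concentration_rejected(self):
        with pytest.raises(ValueError):
            binding_rhs(SystemState(l_op=-1.0), OP, NX)


class TestNaloxonePK:
    def test_zero_state_no_admin_is_stationary(self, subject):
        derivs = naloxone_pk_rhs(SystemState(), subject.naloxone_pk, 10.0, [], 4.0)
        assert derivs == (0.0, 0.0, 0.0)

    def test_mass_balance_total_absorbed_equals_dose_times_f(self, subject):
        """Integrating the absorption flux k_in*T2 over a long horizon must
        recover D*F: the transit chain neither creates nor destroys drug."""
        p = subject.naloxone_pk
        dose = 4.0

        def rhs(t, y):
            st = SystemState(t1=y[0], t2=y[1], p_nx=y[2])
            dt1, dt2, dp = naloxone_pk_rhs(st, p, t, [0.0], dose)
            absorbed_flux = (p.k_in / 60.0) * y[1]
            return [dt1, dt2, dp, absorbed_flux]

        horizon = 40 * 3600.0
        sol = solve_ivp(rhs, (0, horizon), [0, 0, 0, 0], rtol=1e-10, atol=1e-12)
        total_absorbed = sol.y[3, -1]
        assert total_absorbed == pytest.approx(dose * p.f, rel=1e-4)

    def test_linearity_in_dose(self, subject):
        p = subject.naloxone_pk

        def traj(dose):
            def rhs(t, y):
                st = SystemState(t1=y[0], t2=y[1], p_nx=y[2])
                return naloxone_pk_rhs(st, p, t, [0.0], dose)
            return solve_ivp(rhs, (0, 3600), [0, 0, 0], rtol=1e-10,
                             atol=1e-14, t_eval=np.linspace(0, 3600, 20)).y

        np.testing.assert_allclose(traj(8.0), 2.0 * traj(4.0), rtol=1e-6)


class TestOpioidPK:
    def test_zero_state_stationary(self, subject):
        assert opioid_pk_rhs(SystemState(), subject.opioid_pk) == (0.0, 0.0, 0.0)

    def test_mass_conserved_without_elimination(self, subject):
        import dataclasses
        p = dataclasses.replace(subject.opioid_pk, k_out=1e-12)
        def rhs(t, y):
            return opioid_pk_rhs(SystemState(p_f=y[0], p_f2=y[1], p_f3=y[2]), p)
        sol = solve_ivp(rhs, (0, 3600), [0.11, 0, 0], rtol=1e-10, atol=1e-14)
        totals = sol.y.sum(axis=0)
        np.testing.assert_allclose(totals, 0.11, rtol=1e-6)

    def test_matches_matrix_exponential(self, subject):
        """The linear 3-compartment trajectory must agree with the closed
        form expm(A t) @ y0 to 1e-8 relative error."""
        p = subject.opioid_pk
        # oracle rate matrix written out by hand (1/s)
        k_out, k12, k21, k13, k31 = (x / 60.0 for x in
                                     (p.k_out, p.k12, p.k21, p.k13, p.k31))
        A = np.array([
            [-(k12 + k13 + k_out), k21, k31],
            [k12, -k21, 0.0],
            [k13, 0.0, -k31],
        ])
        y0 = np.array([0.11, 0.0, 0.0])
        t_eval = np.linspace(0, 3600, 25)[1:]

        def rhs(t, y):
            return opioid_pk_rhs(SystemState(p_f=y[0], p_f2=y[1], p_f3=y[2]), p)

        sol = solve_ivp(rhs, (0, 3600), y0, method="LSODA",
                        rtol=1e-11, atol=1e-14, t_eval=t_eval)
        exact = np.array([expm(A * t) @ y0 for t in t_eval]).T
        np.testing.assert_allclose(sol.y, exact, rtol=1e-8, atol=1e-14)


class TestBiophase:
    def test_zero_is_stationary(self, subject):
        d = biophase_rhs(SystemState(), subject.opioid_pk, subject.naloxone_pk)
        assert d == (0.0, 0.0)

    def test_converges_to_plasma_concentration_closed_form(self, subject):
        """With the central amount clamped, l(t) relaxes exponentially to
        p_f * 1e9 / (v_c * M) at rate k1."""
        p = subject.opioid_pk
        p_f = 0.05
        target = p_f * 1e9 / (p.v_c * p.molar_mass)
        k1 = p.k1_biophase / 60.0

        def rhs(t, y):
            st = SystemState(p_f=p_f, l_op=y[0])
            return [biophase_rhs(st, p, subject.naloxone_pk)[0]]

        ts = np.linspace(0, 3000, 7)[1:]
        sol = solve_ivp(rhs, (0, 3000), [0.0], rtol=1e-10, atol=1e-8, t_eval=ts)
        expected = target * (1 - np.exp(-k1 * ts))
        np.testing.assert_allclose(sol.y[0], expected, rtol=1e-6)

    def test_unit_conversion_mg_per_l_to_pm(self, subject):
        # 1 mg in 1 L of a 1 g/mol compound is 1e9 pM
        import dataclasses
        op = dataclasses.replace(subject.opioid_pk, v_c=1.0, molar_mass=1.0)
        d_l, _ = biophase_rhs(SystemState(p_f=1.0), op, subject.naloxone_pk)
        assert d_l == pytest.approx((op.k1_biophase / 60.0) * 1e9)


class TestMinuteVentilation:
    @pytest.mark.parametrize("r_op, alpha, expected", [
        (0.0, 1.0, 1.0),
        (0.75, 1.0, 0.25),
        (0.9, 0.0, 1.0),
    ])
    def test_pd_map(self, r_op, alpha, expected):
        assert minute_ventilation(r_op, alpha) == pytest.approx(expected)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            minute_ventilation(1.5, 1.0)
        with pytest.raises(ValueError):
            minute_ventilation(0.5, 2.0)


class TestEquilibriumOccupancy:
    def test_no_ligand(self):
        assert equilibrium_occupancy(0, 0, OP, NX) == (0.0, 0.0)

    def test_single_ligand_half_occupancy_at_kd(self):
        l_op = OP.k_off / OP.k_on  # A = 1
        r_op, r_nx = equilibrium_occupancy(l_op, 0.0, OP, NX)
        assert r_op == pytest.approx(0.5)
        assert r_nx == 0.0

    def test_symmetric_ligands_share_occupancy(self):
        l_op = 3.0 * OP.k_off / OP.k_on
        l_nx = 3.0 * NX.k_off / NX.k_on
        r_op, r_nx = equilibrium_occupancy(l_op, l_nx, OP, NX)
        assert r_op == pytest.approx(r_nx)

    def test_dynamic_occupancy_relaxes_to_equilibrium(self):
        """Clamped-concentration integration must converge to the algebraic
        competitive equilibrium within 1e-4 after 20 relaxation times."""
        l_op, l_nx = 800.0, 2000.0

        def rhs(t, y):
            st = SystemState(l_op=l_op, l_nx=l_nx, r_op=y[0], r_nx=y[1])
            return binding_rhs(st, OP, NX)

        # slowest relaxation rate from the hand-built Jacobian of the
        # coupled linear system (concentrations clamped)
        a_op = OP.k_on * l_op ** OP.n
        a_nx = NX.k_on * l_nx ** NX.n
        jac = np.array([[-(a_op + OP.k_off), -a_op],
                        [-a_nx, -(a_nx + NX.k_off)]])
        rate = min(abs(np.linalg.eigvals(jac).real))
        horizon = 20.0 / rate
        sol = solve_ivp(rhs, (0, horizon), [0, 0], rtol=1e-10, atol=1e-12)
        expected = equilibrium_occupancy(l_op, l_nx, OP, NX)
        np.testing.assert_allclose(sol.y[:, -1], expected, atol=1e-4)

    def test_single_ligand_relaxation_closed_form(self):
        """r(t) = r_eq + (r0 - r_eq) exp(-(k_on L^n + k_off) t)."""
        l_op = 400.0
        rate = OP.k_on * l_op ** OP.n + OP.k_off
        r_eq = equilibrium_occupancy(l_op, 0.0, OP, NX)[0]

        def rhs(t, y):
            st = SystemState(l_op=l_op, r_op=y[0])
            return [binding_rhs(st, OP, NX)[0]]

        ts = np.linspace(0, 10 / rate, 12)[1:]
        sol = solve_ivp(rhs, (0, ts[-1]), [0.0], rtol=1e-12, atol=1e-14,
                        t_eval=ts)
        expected = r_eq * (1 - np.exp(-rate * ts))
        np.testing.assert_allclose(sol.y[0], expected, atol=1e-6)


class TestSimulateSubject:
    def test_no_rescue_scenario_depresses_without_naloxone(self, subject, fast_sim):
        sc = DosingScenario(0.11, 0, 4.0, 0.25, 3.0)
        tc = simulate_subject(subject, sc, fast_sim)
        assert tc.v_f.min() < 1.0
        assert tc.naloxone_admin_times.size == 0

    def test_zero_dose_identity(self, subject, fast_sim):
        sc = DosingScenario(0.0, 1, 4.0, 0.25, 3.0)
        tc = simulate_subject(subject, sc, fast_sim)
        np.testing.assert_allclose(tc.v_f, 1.0, atol=1e-9)
        assert tc.naloxone_admin_times.size == 0

    def test_rescue_reverses_depression(self, subject, rescue_scenario):
        tc = simulate_subject(subject, rescue_scenario)
        assert tc.naloxone_admin_times.size == 1
        t_admin = tc.naloxone_admin_times[0]
        after = tc.times > t_admin
        nadir = np.argmin(tc.v_f)
        assert tc.times[nadir] > t_admin  # nadir (reversal point) after rescue
        assert tc.v_f[-1] > tc.v_f[nadir] + 0.1

    def test_event_localized_within_tolerance(self, subject, rescue_scenario):
        """The administration time must coincide (within event_tol) with the
        time v_f actually crosses the threshold on a fine output grid."""
        config = SimConfig(horizon=600.0, output_step=0.25)
        tc = simulate_subject(subject, rescue_scenario, config)
        t_admin = tc.naloxone_admin_times[0]
        below = np.nonzero(tc.v_f < rescue_scenario.threshold_frac)[0]
        i = below[0]
        t_cross = np.interp(rescue_scenario.threshold_frac,
                            [tc.v_f[i], tc.v_f[i - 1]],
                            [tc.times[i], tc.times[i - 1]])
        assert abs(t_admin - t_cross) <= config.event_tol

    def test_multiple_doses_scheduled_at_delay_multiples(self, subject, fast_sim):
        sc = DosingScenario(0.11, 3, 4.0, 0.25, 2.0)
        tc = simulate_subject(subject, sc, fast_sim)
        assert tc.naloxone_admin_times.size == 3
        gaps = np.diff(tc.naloxone_admin_times)
        np.testing.assert_allclose(gaps, 120.0, atol=1e-9)

    def test_deterministic_bit_identical(self, subject, rescue_scenario, fast_sim):
        a = simulate_subject(subject, rescue_scenario, fast_sim)
        b = simulate_subject(subject, rescue_scenario, fast_sim)
        assert np.array_equal(a.r_op, b.r_op)
        assert np.array_equal(a.v_f, b.v_f)
        assert np.array_equal(a.naloxone_admin_times, b.naloxone_admin_times)

    def test_trajectory_invariants(self, subject, fast_sim):
        """Occupancy fractions stay in [0,1], their sum never exceeds 1."""
        for dose in (0.013, 0.157):
            for n_dose in (0, 2):
                sc = DosingScenario(dose, n_dose, 4.0, 0.4, 2.0)
                tc = simulate_subject(subject, sc, fast_sim)
                assert np.all(tc.r_op >= 0) and np.all(tc.r_op <= 1)
                assert np.all(tc.v_f >= 0) and np.all(tc.v_f <= 1)
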