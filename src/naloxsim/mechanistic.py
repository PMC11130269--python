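"""Coupled PK-receptor-PD simulation for one subject under one dosing scenario.

The system couples:

* intranasal naloxone PK — two transit compartments (T1, T2, mg) feeding a
  central concentration P (mg/L), driven by a first-order input
  k_tr * D * F * exp(-k_tr (t - t_d)) for each administration at t_d;
* IV-bolus opioid PK — a linear three-compartment model in amounts (mg),
  with the bolus entering as the initial central amount;
* biophase transition — first-order equilibration of each drug's effect-site
  concentration (pM) with its central compartment;
* competitive receptor binding — two Hill-type association/dissociation
  equations sharing the free receptor fraction R = 1 - r_op - r_nx;
* the PD map v_f = 1 - alpha * r_op from opioid occupancy to fractional
  minute ventilation.

Naloxone administration is event-triggered: the first dose is given when v_f
first falls through the scenario threshold, subsequent doses at fixed delays
after it.  The integration is piecewise between administration times so the
discontinuous forcing never crosses a solver step.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import exp
from typing import Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .params import (
    DosingScenario,
    LigandBindingParams,
    NaloxonePKParams,
    OpioidPKParams,
    SimConfig,
    TimeCourse,
    VirtualSubject,
)

__all__ = [
    "SystemState",
    "SimulationError",
    "binding_rhs",
    "naloxone_pk_rhs",
    "opioid_pk_rhs",
    "biophase_rhs",
    "minute_ventilation",
    "equilibrium_occupancy",
    "simulate_subject",
]

# state vector layout
_T1, _T2, _P_NX, _P_F, _P_F2, _P_F3, _L_OP, _L_NX, _R_OP, _R_NX = range(10)
N_STATE = 10


class SimulationError(RuntimeError):
    """Integrator failure, carrying enough context to identify the run."""

    def __init__(self, message: str, subject=None, scenario=None):
        super().__init__(message)
        self.subject = subject
        self.scenario = scenario


@dataclass
class SystemState:
    """Full state of the coupled system at one instant.

    t1, t2 : naloxone transit amounts (mg); p_nx : naloxone central
    concentration (mg/L); p_f, p_f2, p_f3 : opioid compartment amounts (mg);
    l_op, l_nx : effect-site concentrations (pM); r_op, r_nx : bound receptor
    fractions.  The free receptor fraction is R = 1 - r_op - r_nx.
    """

    t1: float = 0.0
    t2: float = 0.0
    p_nx: float = 0.0
    p_f: float = 0.0
    p_f2: float = 0.0
    p_f3: float = 0.0
    l_op: float = 0.0
    l_nx: float = 0.0
    r_op: float = 0.0
    r_nx: float = 0.0

    def to_array(self) -> np.ndarray:
        return np.array([self.t1, self.t2, self.p_nx, self.p_f, self.p_f2,
                         self.p_f3, self.l_op, self.l_nx, self.r_op, self.r_nx])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "SystemState":
        return cls(*map(float, y))


def binding_rhs(
    state: SystemState,
    op: LigandBindingParams,
    nx: LigandBindingParams,
) -> tuple[float, float]:
    """Time derivatives of the two bound-receptor fractions (per second).

    dr_op/dt = k_on_op * l_op^n_op * (1 - r_op - r_nx) - k_off_op * r_op,
    and symmetrically for naloxone; the two ligands compete for the shared
    free fraction.
    """
    if state.l_op < 0 or state.l_nx < 0:
        raise ValueError("effect-site concentrations must be non-negative")
    free = 1.0 - state.r_op - state.r_nx
    dr_op = op.k_on * state.l_op ** op.n * free - op.k_off * state.r_op
    dr_nx = nx.k_on * state.l_nx ** nx.n * free - nx.k_off * state.r_nx
    return dr_op, dr_nx


def naloxone_pk_rhs(
    state: SystemState,
    params: NaloxonePKParams,
    t: float,
    admin_times: Sequence[float],
    dose: float,
) -> tuple[float, float, float]:
    """Transit-chain derivatives (per second) at time t (seconds).

    Each administration at t_d <= t contributes a forcing term
    k_tr * D * F * exp(-k_tr (t - t_d)) into the first transit compartment;
    contributions superpose because the chain is linear in the input.
    """
    k_tr = params.k_tr / 60.0
    k_in = params.k_in / 60.0
    c_l = params.c_l / 60.0
    forcing = 0.0
    for t_d in admin_times:
        if t_d <= t:
            forcing += k_tr * dose * params.f * exp(-k_tr * (t - t_d))
    dt1 = forcing - k_tr * state.t1
    dt2 = k_tr * state.t1 - k_in * state.t2
    dp = (k_in / params.v) * state.t2 - (c_l / params.v) * state.p_nx
    return dt1, dt2, dp


def opioid_pk_rhs(
    state: SystemState, params: OpioidPKParams
) -> tuple[float, float, float]:
    """Linear three-compartment derivatives (mg/s); bolus enters as p_f(0)."""
    k_out = params.k_out / 60.0
    k12 = params.k12 / 60.0
    k21 = params.k21 / 60.0
    k13 = params.k13 / 60.0
    k31 = params.k31 / 60.0
    dp_f = k21 * state.p_f2 + k31 * state.p_f3 - (k12 + k13 + k_out) * state.p_f
    dp_f2 = k12 * state.p_f - k21 * state.p_f2
    dp_f3 = k13 * state.p_f - k31 * state.p_f3
    return dp_f, dp_f2, dp_f3


def biophase_rhs(
    state: SystemState, op: OpioidPKParams, nx: NaloxonePKParams
) -> tuple[float, float]:
    """Effect-site equilibration derivatives (pM/s).

    The opioid central amount p_f (mg) over v_c (L) and molar mass (g/mol)
    gives the plasma concentration in pM after the 1e9 scaling
    (1 mg / (L * g/mol) = 1e9 pM); the naloxone central compartment is
    already a concentration (mg/L) so only the molar-mass conversion applies.
    """
    k1_op = op.k1_biophase / 60.0
    k1_nx = nx.k1_biophase / 60.0
    c_op_pm = state.p_f * 1e9 / (op.v_c * op.molar_mass)
    c_nx_pm = state.p_nx * 1e9 / nx.molar_mass
    dl_op = k1_op * (c_op_pm - state.l_op)
    dl_nx = k1_nx * (c_nx_pm - state.l_nx)
    return dl_op, dl_nx


def minute_ventilation(r_op: float, alpha: float) -> float:
    """PD map: fractional minute ventilation v_f = 1 - alpha * r_op."""
    r = np.asarray(r_op, dtype=float)
    if np.any(r < 0) or np.any(r > 1):
        raise ValueError("occupancy must lie in [0, 1]")
    if not 0 <= alpha <= 1:
        raise ValueError("alpha must lie in [0, 1]")
    out = 1.0 - alpha * r
    return float(out) if np.isscalar(r_op) else out


def equilibrium_occupancy(
    l_op: float,
    l_nx: float,
    op: LigandBindingParams,
    nx: LigandBindingParams,
) -> tuple[float, float]:
    """Steady-state occupancies under clamped effect-site concentrations.

    With A = k_on_op l_op^n_op / k_off_op and B defined analogously for
    naloxone, the competitive equilibrium is (A, B) / (1 + A + B).
    """
    if l_op < 0 or l_nx < 0:
        raise ValueError("concentrations must be non-negative")
    a = op.k_on * l_op ** op.n / op.k_off
    b = nx.k_on * l_nx ** nx.n / nx.k_off
    denom = 1.0 + a + b
    return a / denom, b / denom


# ---------------------------------------------------------------------------
# Full-system right-hand side (array form, used by the integrator)


def _make_rhs(subject: VirtualSubject, admin_times: tuple[float, ...], dose: float):
    opb, nxb = subject.opioid_binding, subject.naloxone_binding
    opk, nxk = subject.opioid_pk, subject.naloxone_pk
    # pre-convert to per-second rates once; the closure works on plain floats
    k_tr = nxk.k_tr / 60.0
    k_in = nxk.k_in / 60.0
    cl_v = nxk.c_l / 60.0 / nxk.v
    kin_v = k_in / nxk.v
    df = dose * nxk.f
    k_out = opk.k_out / 60.0
    k12 = opk.k12 / 60.0
    k21 = opk.k21 / 60.0
    k13 = opk.k13 / 60.0
    k31 = opk.k31 / 60.0
    k1_op = opk.k1_biophase / 60.0
    k1_nx = nxk.k1_biophase / 60.0
    conv_op = 1e9 / (opk.v_c * opk.molar_mass)
    conv_nx = 1e9 / nxk.molar_mass
    kon_op, koff_op, n_op = opb.k_on, opb.k_off, opb.n
    kon_nx, koff_nx, n_nx = nxb.k_on, nxb.k_off, nxb.n

    def rhs(t, y):
        t1, t2, p_nx, p_f, p_f2, p_f3, l_op, l_nx, r_op, r_nx = y
        forcing = 0.0
        for t_d in admin_times:
            if t_d <= t:
                forcing += k_tr * df * exp(-k_tr * (t - t_d))
        free = 1.0 - r_op - r_nx
        l_op_eff = l_op if l_op > 0.0 else 0.0
        l_nx_eff = l_nx if l_nx > 0.0 else 0.0
        return (
            forcing - k_tr * t1,
            k_tr * t1 - k_in * t2,
            kin_v * t2 - cl_v * p_nx,
            k21 * p_f2 + k31 * p_f3 - (k12 + k13 + k_out) * p_f,
            k12 * p_f - k21 * p_f2,
            k13 * p_f - k31 * p_f3,
            k1_op * (p_f * conv_op - l_op),
            k1_nx * (p_nx * conv_nx - l_nx),
            kon_op * l_op_eff ** n_op * free - koff_op * r_op,
            kon_nx * l_nx_eff ** n_nx * free - koff_nx * r_nx,
        )

    return rhs


def _solve_segment(rhs, t0, t1, y0, config, subject, scenario, events=None):
    if t1 <= t0:
        raise SimulationError("empty integration segment", subject, scenario)
    sol = solve_ivp(
        rhs,
        (t0, t1),
        y0,
        method="LSODA",
        rtol=config.rtol,
        atol=config.atol,
        dense_output=True,
        events=events,
    )
    if not sol.success:
        raise SimulationError(
            f"integration failed on [{t0:.1f}, {t1:.1f}] s: {sol.message}",
            subject,
            scenario,
        )
    return sol


def simulate_subject(
    subject: VirtualSubject,
    scenario: DosingScenario,
    config: SimConfig | None = None,
) -> TimeCourse:
    """Integrate the coupled system and return trajectories on the fixed grid.

    The first naloxone administration is placed at the first downward
    crossing of v_f through the scenario threshold (localized by the
    integrator's root finder); dose k of n lands at t_cross + (k-1) * delay.
    If v_f never reaches the threshold, no naloxone is given.
    """
    config = config or SimConfig()
    grid = config.grid
    alpha = subject.opioid_pk.alpha
    threshold = scenario.threshold_frac

    y0 = np.zeros(N_STATE)
    y0[_P_F] = scenario.opioid_dose

    give_naloxone = (
        scenario.n_naloxone_doses > 0 and scenario.naloxone_dose_per_admin > 0
    )
    rhs_free = _make_rhs(subject, (), scenario.naloxone_dose_per_admin)

    segments = []  # (t_start, t_end, dense solution)
    admin_times: list[float] = []

    if give_naloxone:
        def crossing(t, y):
            return (1.0 - alpha * y[_R_OP]) - threshold

        crossing.terminal = True
        crossing.direction = -1
        sol = _solve_segment(rhs_free, 0.0, config.horizon, y0,
                             config, subject, scenario, events=[crossing])
        if sol.t_events[0].size:
            t_cross = float(sol.t_events[0][0])
            delay_s = scenario.inter_dose_delay * 60.0
            admin_times = [
                t_cross + k * delay_s
                for k in range(scenario.n_naloxone_doses)
                if t_cross + k * delay_s < config.horizon
            ]
            segments.append((0.0, t_cross, sol))
            rhs_dosed = _make_rhs(subject, tuple(admin_times),
                                  scenario.naloxone_dose_per_admin)
            # integrate piecewise between administrations so the forcing
            # discontinuity always falls on a segment boundary
            knots = [t for t in admin_times if t > t_cross] + [config.horizon]
            t_prev = t_cross
            y_prev = sol.y_events[0][0]
            for t_next in knots:
                if t_next <= t_prev:
                    continue
                seg = _solve_segment(rhs_dosed, t_prev, t_next, y_prev,
                                     config, subject, scenario)
                segments.append((t_prev, t_next, seg))
                t_prev = t_next
                y_prev = seg.y[:, -1]
        else:
            segments.append((0.0, config.horizon, sol))
    else:
        sol = _solve_segment(rhs_free, 0.0, config.horizon, y0,
                             config, subject, scenario)
        segments.append((0.0, config.horizon, sol))

    # evaluate the dense solutions on the fixed output grid
    r_op = np.empty_like(grid)
    for t_start, t_end, sol in segments:
        mask = (grid >= t_start) & (grid <= t_end)
        if mask.any():
            r_op[mask] = sol.sol(grid[mask])[_R_OP]
    r_op = np.clip(r_op, 0.0, 1.0)
    v_f = np.clip(1.0 - alpha * r_op, 0.0, 1.0)
    return TimeCourse(grid, r_op, v_f, np.array(admin_times))
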