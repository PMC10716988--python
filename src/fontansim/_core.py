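"""Numba-compiled right-hand side and beat-by-beat integrator.

The circulation is an 8-state ODE advanced with a fixed-step classical
Runge-Kutta (RK4) scheme.  State vector (all volumes are stressed
volumes in ml, flow in ml/s, time in seconds inside this module):

    y = [V_earlier, V_delayed, V_atrium,
         V_Cart_sys, V_Cven_sys, V_Cart_pul, V_Cven_pul, Q_av]

The parameter vector layout is defined by :func:`pack_params` in
``circuit.py``; index constants below must stay in sync with it.
Integration proceeds one beat at a time; the last integrated beat's state
trajectory is recorded on the step grid and beat-to-beat drift of
end-diastolic volume and forward stroke output decides convergence.
Summed volume derivatives cancel pairwise, so RK4 conserves total
stressed volume to round-off.
"""

import numpy as np
from numba import njit

# parameter-vector indices (see circuit.pack_params)
IEMAX_E, IB_E, IV0_E = 0, 1, 2
IEMAX_D, IB_D, IV0_D = 3, 4, 5
IA_V, ITMAX_V = 6, 7
IEMAX_A, IA_A, IB_A, IV0_A, ITMAX_A = 8, 9, 10, 11, 12
IZART, ICART, IRART, ICVEN, IRVEN = 13, 14, 15, 16, 17
IZPA, ICPA, IRPA, ICPV, IRPV = 18, 19, 20, 21, 22
IEOA, IL, IRHO, IK = 23, 24, 25, 26
IRAO, IRIC = 27, 28
ITCYC, ION_A, ION_E, ION_D, IRELAX = 29, 30, 31, 32, 33
IINFLOW_D, IOUTFLOW_E = 34, 35
NPARAMS = 36


@njit(cache=True)
def activation(t, onset, tmax, tcyc, relax):
    ph = (t - onset) % tcyc
    if ph < tmax:
        return 0.5 * (1.0 - np.cos(np.pi * ph / tmax))
    elif ph < (1.0 + relax) * tmax:
        return 0.5 * (1.0 + np.cos(np.pi * (ph - tmax) / (relax * tmax)))
    return 0.0


@njit(cache=True)
def chamber_pressure(v, e, emax, a, b, v0):
    ped = a * (np.exp(b * (v - v0)) - 1.0)
    pes = emax * (v - v0)
    return ped + e * (pes - ped)


@njit(cache=True)
def rhs(t, y, pp, dy):
    e_e = activation(t, pp[ION_E], pp[ITMAX_V], pp[ITCYC], pp[IRELAX])
    e_d = activation(t, pp[ION_D], pp[ITMAX_V], pp[ITCYC], pp[IRELAX])
    e_a = activation(t, pp[ION_A], pp[ITMAX_A], pp[ITCYC], pp[IRELAX])
    p_e = chamber_pressure(y[0], e_e, pp[IEMAX_E], pp[IA_V], pp[IB_E], pp[IV0_E])
    p_d = chamber_pressure(y[1], e_d, pp[IEMAX_D], pp[IA_V], pp[IB_D], pp[IV0_D])
    p_a = chamber_pressure(y[2], e_a, pp[IEMAX_A], pp[IA_A], pp[IB_A], pp[IV0_A])
    p_ca = y[3] / pp[ICART]
    p_cv = y[4] / pp[ICVEN]
    p_cpa = y[5] / pp[ICPA]
    p_cpv = y[6] / pp[ICPV]

    p_out = p_e if pp[IOUTFLOW_E] > 0.5 else p_d
    q_ao = (p_out - p_ca) / (pp[IRAO] + pp[IZART])
    if q_ao < 0.0:
        q_ao = 0.0
    q_sys = (p_ca - p_cv) / pp[IRART]
    q_pin = (p_cv - p_cpa) / (pp[IRVEN] + pp[IZPA])
    q_pa = (p_cpa - p_cpv) / pp[IRPA]
    q_pv = (p_cpv - p_a) / pp[IRPV]
    q_ic = (p_e - p_d) / pp[IRIC]

    p_in = p_d if pp[IINFLOW_D] > 0.5 else p_e
    q_av = y[7] if y[7] > 0.0 else 0.0
    if y[7] > 0.0 or p_a > p_in:
        dq = (p_a - p_in - pp[IRHO] * q_av * abs(q_av)
              / (2.0 * pp[IK] * pp[IEOA] * pp[IEOA])) / pp[IL]
    else:
        dq = 0.0

    dy[0] = -q_ic
    dy[1] = q_ic
    if pp[IINFLOW_D] > 0.5:
        dy[1] += q_av
    else:
        dy[0] += q_av
    if pp[IOUTFLOW_E] > 0.5:
        dy[0] -= q_ao
    else:
        dy[1] -= q_ao
    dy[2] = q_pv - q_av
    dy[3] = q_ao - q_sys
    dy[4] = q_sys - q_pin
    dy[5] = q_pin - q_pa
    dy[6] = q_pa - q_pv
    dy[7] = dq
    return q_ao


@njit(cache=True)
def _rk4_step(t, y, pp, dt, k1, k2, k3, k4, tmp):
    rhs(t, y, pp, k1)
    for j in range(8):
        tmp[j] = y[j] + 0.5 * dt * k1[j]
    rhs(t + 0.5 * dt, tmp, pp, k2)
    for j in range(8):
        tmp[j] = y[j] + 0.5 * dt * k2[j]
    rhs(t + 0.5 * dt, tmp, pp, k3)
    for j in range(8):
        tmp[j] = y[j] + dt * k3[j]
    rhs(t + dt, tmp, pp, k4)
    for j in range(8):
        y[j] += dt / 6.0 * (k1[j] + 2.0 * k2[j] + 2.0 * k3[j] + k4[j])
    if y[7] < 0.0:
        y[7] = 0.0


@njit(cache=True)
def run_beats(pp, y0, dt, max_beats, min_beats, tol):
    """Integrate beat by beat until periodic convergence.

    Returns ``(states, n_beats, drift_edv, drift_sv, converged)`` where
    ``states`` is an ``(nstep+1, 9)`` array of ``[t, y0..y7]`` samples of
    the last integrated beat and the drifts are the relative beat-to-beat
    changes of end-diastolic volume and forward stroke output at exit.
    """
    tcyc = pp[ITCYC]
    nstep = int(round(tcyc / dt))
    y = y0.copy()
    k1 = np.empty(8); k2 = np.empty(8); k3 = np.empty(8); k4 = np.empty(8)
    tmp = np.empty(8)
    dyv = np.empty(8)
    states = np.empty((nstep + 1, 9))
    edv_prev = -1.0
    sv_prev = -1.0
    drift_edv = np.inf
    drift_sv = np.inf
    converged = False
    n_beats = 0
    for b in range(max_beats):
        edv = -1.0
        sv = 0.0
        for i in range(nstep):
            t = i * dt
            states[i, 0] = t
            for j in range(8):
                states[i, 1 + j] = y[j]
            vtot = y[0] + y[1]
            if vtot > edv:
                edv = vtot
            q_ao = rhs(t, y, pp, dyv)
            sv += q_ao * dt
            _rk4_step(t, y, pp, dt, k1, k2, k3, k4, tmp)
            if not np.isfinite(y[0]):
                return states, b + 1, np.nan, np.nan, False
        states[nstep, 0] = nstep * dt
        for j in range(8):
            states[nstep, 1 + j] = y[j]
        n_beats = b + 1
        if edv_prev > 0.0:
            drift_edv = abs(edv - edv_prev) / edv
            drift_sv = abs(sv - sv_prev) / max(sv, 1e-9)
            if n_beats >= min_beats and drift_edv < tol and drift_sv < tol:
                converged = True
                break
        edv_prev = edv
        sv_prev = sv
    return states, n_beats, drift_edv, drift_sv, converged
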