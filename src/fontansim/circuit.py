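"""Closed-loop 0D model of the Fontan (total cavopulmonary) circulation.

Topology
--------
The loop has seven volume stores and one inertial flow state::

    ventricle (earlier + delayed compartments, coupled through R_ic)
      --aortic valve (diode + R_ao)--> ascending aorta
      --Z_art--> systemic arterial compliance --R_art--> systemic venous
      compliance --R_ven--> [CVP node, the SVC/TCPC junction]
      --Z_pa--> pulmonary arterial compliance --R_pa--> pulmonary venous
      compliance --R_pv--> atrium --AV valve (Bernoulli orifice + L)-->
      earlier compartment

There is no subpulmonary ventricle: systemic venous return drains
passively through the lungs, so the central venous pressure is read at
the junction downstream of the systemic venous resistance where the
caval veins meet the pulmonary artery.  Atrioventricular inflow enters
the earlier-activated compartment and aortic outflow leaves the delayed
compartment (the delayed wall carries the outflow tract); both
assignments are configurable.

Node pressures follow from stressed volumes (``P = V/C`` for the
vascular stores, the time-varying elastance law for the chambers);
inter-node flows are Ohmic except for the two valves.  Both valves are
diodes: flows are clamped non-negative and the AV inertial state resets
to zero on closure.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from . import _core
from .chambers import (
    ChamberParams,
    N_VENTRICLE_UNITS,
    compartment_parameters,
    instantaneous_pressure,
)
from .config import CircuitParams

__all__ = [
    "CircuitState",
    "BeatTraces",
    "BeatMetrics",
    "ConvergenceError",
    "av_valve_pressure_drop",
    "derivatives",
    "simulate_to_steady_state",
    "beat_metrics",
    "count_reverse_flow_bursts",
]


class ConvergenceError(RuntimeError):
    """Periodic steady state not reached; carries the last-beat drift."""

    def __init__(self, msg: str, drift_edv: float, drift_sv: float):
        super().__init__(msg)
        self.drift_edv = drift_edv
        self.drift_sv = drift_sv


@dataclass
class CircuitState:
    """Instantaneous stressed volumes (ml) and AV valve flow (ml/s)."""

    v_earlier: float
    v_delayed: float
    v_atrium: float
    v_sys_art: float
    v_sys_ven: float
    v_pul_art: float
    v_pul_ven: float
    q_av: float

    def as_array(self) -> np.ndarray:
        return np.array([
            self.v_earlier, self.v_delayed, self.v_atrium, self.v_sys_art,
            self.v_sys_ven, self.v_pul_art, self.v_pul_ven, self.q_av,
        ])

    @classmethod
    def from_array(cls, y: np.ndarray) -> "CircuitState":
        return cls(*[float(v) for v in y])

    @property
    def total_volume(self) -> float:
        return (self.v_earlier + self.v_delayed + self.v_atrium + self.v_sys_art
                + self.v_sys_ven + self.v_pul_art + self.v_pul_ven)


@dataclass
class BeatTraces:
    """One steady-state beat on a uniform time grid (t = 0 at atrial onset)."""

    t_ms: np.ndarray
    v_e: np.ndarray
    v_d: np.ndarray
    v_atrium: np.ndarray
    p_e: np.ndarray
    p_d: np.ndarray
    p_atrium: np.ndarray
    p_ao: np.ndarray       # ascending aorta (distal to the aortic valve)
    p_art: np.ndarray      # systemic arterial compliance node
    p_cvp: np.ndarray      # SVC/TCPC junction (central venous pressure site)
    p_sys_ven: np.ndarray  # systemic venous compliance node
    p_pa: np.ndarray
    p_pv: np.ndarray
    q_av: np.ndarray
    q_ao: np.ndarray
    q_ic: np.ndarray       # intercompartment flow, positive = earlier -> delayed
    events: dict = field(default_factory=dict)
    n_beats: int = 0
    drift_edv: float = np.nan
    drift_sv: float = np.nan
    converged: bool = False

    @property
    def v_total(self) -> np.ndarray:
        return self.v_e + self.v_d

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "t_ms": self.t_ms, "V_e": self.v_e, "V_d": self.v_d,
            "V_atrium": self.v_atrium, "P_e": self.p_e, "P_d": self.p_d,
            "P_atrium": self.p_atrium, "P_ao": self.p_ao, "P_art": self.p_art,
            "P_cvp": self.p_cvp, "P_pa": self.p_pa, "P_pv": self.p_pv,
            "Q_av": self.q_av, "Q_ao": self.q_ao, "Q_ic": self.q_ic,
        })


@dataclass
class BeatMetrics:
    """Per-beat hemodynamic summary of a converged steady-state beat."""

    edv: float                  # max total ventricular volume, ml
    edv_at_onset: float         # total volume at earlier activation onset, ml
    esv: float                  # total volume at aortic valve closure, ml
    ef: float                   # %
    sv: float                   # forward aortic output per beat, ml
    co: float                   # L/min
    ci: float                   # L/min/m^2
    mean_cvp: float
    mean_atrial_p: float
    esp: float                  # peak pressure of the outflow compartment, mmHg
    p_at_aortic_closure: float
    edp: float                  # ventricular pressure at earlier onset, mmHg
    arterial_sys: float
    arterial_dia: float
    arterial_mean: float
    dpdt_max: float             # mmHg/s, outflow compartment
    effective_ees: float        # mmHg/ml, single-beat elastance surrogate
    pvri: float                 # units.m^2
    svri: float                 # units.m^2
    reverse_flow_pct: float     # % of baseline per-beat output
    hr: float
    bsa: float


def av_valve_pressure_drop(Q, EOA: float, rho: float = 1.06, K: float = 1333.0):
    """Bernoulli orifice loss ``rho Q^2 / (2 K EOA^2)`` in mmHg for Q >= 0."""
    if EOA <= 0:
        raise ValueError("EOA must be positive")
    Q = np.asarray(Q, dtype=float)
    if np.any(Q < 0):
        raise ValueError("Q must be non-negative (closed valve is handled by flow-state logic)")
    out = rho * Q**2 / (2.0 * K * EOA**2)
    return float(out) if out.ndim == 0 else out


def _compartments(p: CircuitParams) -> tuple[ChamberParams, ChamberParams]:
    f_d = p.delayed_fraction
    earlier = compartment_parameters(1.0 - f_d, p.ventricle_unit, p.continuous_fraction)
    delayed = compartment_parameters(f_d, p.ventricle_unit, p.continuous_fraction)
    return earlier, delayed


def pack_params(p: CircuitParams) -> np.ndarray:
    """Flatten CircuitParams into the integrator's parameter vector (SI-seconds)."""
    earlier, delayed = _compartments(p)
    pp = np.empty(_core.NPARAMS)
    pp[_core.IEMAX_E], pp[_core.IB_E], pp[_core.IV0_E] = earlier.Emax, earlier.B, earlier.V0
    pp[_core.IEMAX_D], pp[_core.IB_D], pp[_core.IV0_D] = delayed.Emax, delayed.B, delayed.V0
    pp[_core.IA_V] = p.ventricle_unit.A
    pp[_core.ITMAX_V] = p.ventricle_unit.Tmax / 1000.0
    a = p.atrium
    pp[_core.IEMAX_A], pp[_core.IA_A], pp[_core.IB_A] = a.Emax, a.A, a.B
    pp[_core.IV0_A], pp[_core.ITMAX_A] = a.V0, a.Tmax / 1000.0
    s, pu = p.systemic, p.pulmonary
    pp[_core.IZART], pp[_core.ICART], pp[_core.IRART] = s.Z_art, s.C_art, s.R_art
    pp[_core.ICVEN], pp[_core.IRVEN] = s.C_ven, s.R_ven
    pp[_core.IZPA], pp[_core.ICPA], pp[_core.IRPA] = pu.Z_art, pu.C_art, pu.R_art
    pp[_core.ICPV], pp[_core.IRPV] = pu.C_ven, pu.R_ven
    v = p.av_valve
    pp[_core.IEOA], pp[_core.IL], pp[_core.IRHO], pp[_core.IK] = v.EOA, v.L, v.rho, v.K
    pp[_core.IRAO], pp[_core.IRIC] = p.aortic_valve_R, p.intercompartment_R
    pp[_core.ITCYC] = 60.0 / p.HR
    pp[_core.ION_A] = 0.0
    pp[_core.ION_E] = p.PR / 1000.0
    pp[_core.ION_D] = (p.PR + p.delay_dT) / 1000.0
    pp[_core.IRELAX] = p.relax_ratio
    pp[_core.IINFLOW_D] = 1.0 if p.inflow_compartment == "delayed" else 0.0
    pp[_core.IOUTFLOW_E] = 1.0 if p.outflow_compartment == "earlier" else 0.0
    return pp


def initial_state(p: CircuitParams) -> CircuitState:
    """Documented initial volume allocation.

    The ventricle starts at the passive volume corresponding to a filling
    pressure of 8 mmHg (split between compartments by their fractions),
    the atrium at 36 ml, and the remaining stressed volume is distributed
    over the four vascular stores in proportion to compliance times a
    nominal pressure profile (87 / 13.3 / 9.3 / 6.5 mmHg), then rescaled
    so the total equals ``total_stressed_volume`` exactly.
    """
    f_d = p.delayed_fraction
    b_tot = p.ventricle_unit.B / N_VENTRICLE_UNITS
    v0_tot = p.ventricle_unit.V0 * N_VENTRICLE_UNITS
    v_vent = v0_tot + np.log(8.0 / p.ventricle_unit.A + 1.0) / b_tot
    v_atr = 36.0
    nominal = np.array([
        p.systemic.C_art * 87.0, p.systemic.C_ven * 13.3,
        p.pulmonary.C_art * 9.3, p.pulmonary.C_ven * 6.5,
    ])
    remaining = p.total_stressed_volume - v_vent - v_atr
    if remaining <= 0:
        raise ValueError("total_stressed_volume too small for the chamber allocation")
    nominal *= remaining / nominal.sum()
    return CircuitState(
        v_earlier=(1.0 - f_d) * v_vent, v_delayed=f_d * v_vent, v_atrium=v_atr,
        v_sys_art=nominal[0], v_sys_ven=nominal[1],
        v_pul_art=nominal[2], v_pul_ven=nominal[3], q_av=0.0,
    )


def derivatives(state: CircuitState, t: float, p: CircuitParams) -> CircuitState:
    """Time derivative of the circuit state at time ``t`` (seconds).

    Pure-Python reference implementation of the model equations; the
    compiled kernel in ``_core`` is cross-checked against it.  Returns a
    ``CircuitState`` whose fields are rates of change (volume stores in
    ml/s, ``q_av`` in ml/s^2).  The seven volume derivatives sum to zero
    by construction.
    """
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise ValueError(f"non-finite circuit state: {y}")
    earlier, delayed = _compartments(p)
    t_ms = t * 1000.0
    cyc = p.cycle_length_ms
    p_e = instantaneous_pressure(state.v_earlier, (t_ms - p.PR) % cyc, earlier, p.relax_ratio)
    p_d = instantaneous_pressure(
        state.v_delayed, (t_ms - p.PR - p.delay_dT) % cyc, delayed, p.relax_ratio)
    p_a = instantaneous_pressure(state.v_atrium, t_ms % cyc, p.atrium, p.relax_ratio)
    p_ca = state.v_sys_art / p.systemic.C_art
    p_cv = state.v_sys_ven / p.systemic.C_ven
    p_cpa = state.v_pul_art / p.pulmonary.C_art
    p_cpv = state.v_pul_ven / p.pulmonary.C_ven

    p_out = p_e if p.outflow_compartment == "earlier" else p_d
    q_ao = max(0.0, (p_out - p_ca) / (p.aortic_valve_R + p.systemic.Z_art))
    q_sys = (p_ca - p_cv) / p.systemic.R_art
    q_pin = (p_cv - p_cpa) / (p.systemic.R_ven + p.pulmonary.Z_art)
    q_pa = (p_cpa - p_cpv) / p.pulmonary.R_art
    q_pv = (p_cpv - p_a) / p.pulmonary.R_ven
    q_ic = (p_e - p_d) / p.intercompartment_R

    p_in = p_e if p.inflow_compartment == "earlier" else p_d
    q_av = max(0.0, state.q_av)
    if state.q_av > 0.0 or p_a > p_in:
        dq = (p_a - p_in - np.sign(q_av) * av_valve_pressure_drop(
            abs(q_av), p.av_valve.EOA, p.av_valve.rho, p.av_valve.K)) / p.av_valve.L
    else:
        dq = 0.0

    dv_e = -q_ic + (q_av if p.inflow_compartment == "earlier" else 0.0) \
        - (q_ao if p.outflow_compartment == "earlier" else 0.0)
    dv_d = q_ic + (q_av if p.inflow_compartment == "delayed" else 0.0) \
        - (q_ao if p.outflow_compartment == "delayed" else 0.0)
    return CircuitState(
        v_earlier=dv_e, v_delayed=dv_d, v_atrium=q_pv - q_av,
        v_sys_art=q_ao - q_sys, v_sys_ven=q_sys - q_pin,
        v_pul_art=q_pin - q_pa, v_pul_ven=q_pa - q_pv, q_av=dq,
    )


def _derive_traces(states: np.ndarray, p: CircuitParams) -> BeatTraces:
    """Reconstruct pressures/flows from recorded state samples."""
    earlier, delayed = _compartments(p)
    t_s = states[:, 0]
    t_ms = t_s * 1000.0
    v_e, v_d, v_a = states[:, 1], states[:, 2], states[:, 3]
    v_ca, v_cv, v_cpa, v_cpv = states[:, 4], states[:, 5], states[:, 6], states[:, 7]
    q_av = np.clip(states[:, 8], 0.0, None)
    cyc = p.cycle_length_ms
    p_e = instantaneous_pressure(v_e, (t_ms - p.PR) % cyc, earlier, p.relax_ratio)
    p_d = instantaneous_pressure(v_d, (t_ms - p.PR - p.delay_dT) % cyc, delayed, p.relax_ratio)
    p_a = instantaneous_pressure(v_a, t_ms % cyc, p.atrium, p.relax_ratio)
    p_ca = v_ca / p.systemic.C_art
    p_cv = v_cv / p.systemic.C_ven
    p_cpa = v_cpa / p.pulmonary.C_art
    p_cpv = v_cpv / p.pulmonary.C_ven
    p_out = p_e if p.outflow_compartment == "earlier" else p_d
    q_ao = np.clip((p_out - p_ca) / (p.aortic_valve_R + p.systemic.Z_art), 0.0, None)
    q_pin = (p_cv - p_cpa) / (p.systemic.R_ven + p.pulmonary.Z_art)
    return BeatTraces(
        t_ms=t_ms, v_e=v_e, v_d=v_d, v_atrium=v_a,
        p_e=p_e, p_d=p_d, p_atrium=p_a,
        p_ao=p_ca + q_ao * p.systemic.Z_art, p_art=p_ca,
        p_cvp=p_cv - q_pin * p.systemic.R_ven, p_sys_ven=p_cv,
        p_pa=p_cpa, p_pv=p_cpv,
        q_av=q_av, q_ao=q_ao, q_ic=(p_e - p_d) / p.intercompartment_R,
    )


def _flow_events(t_ms: np.ndarray, q: np.ndarray, prefix: str) -> dict:
    open_mask = q > 1e-9
    ev: dict = {}
    if not open_mask.any():
        return ev
    edges = np.diff(open_mask.astype(int))
    rises = np.where(edges == 1)[0] + 1
    falls = np.where(edges == -1)[0] + 1
    if rises.size:
        ev[f"{prefix}_open_ms"] = float(t_ms[rises[0]])
    elif open_mask[0]:
        ev[f"{prefix}_open_ms"] = float(t_ms[0])
    if falls.size:
        ev[f"{prefix}_close_ms"] = float(t_ms[falls[-1]])
    return ev


def simulate_to_steady_state(
    p: CircuitParams,
    dt_ms: float = 0.05,
    min_beats: int = 30,
    max_beats: int = 300,
    tol: float = 1e-5,
    initial: Optional[CircuitState] = None,
    raise_on_nonconvergence: bool = True,
) -> BeatTraces:
    """Integrate the closed loop to periodic steady state; return the final beat.

    Beats are integrated with fixed-step RK4 (``dt_ms`` step) from the
    documented initial allocation until the beat-to-beat relative changes
    of end-diastolic volume and forward stroke output both fall below
    ``tol`` (after at least ``min_beats`` beats, at most ``max_beats``).
    If the integration produces non-finite values the step is halved and
    the run restarted (twice at most).
    """
    pp = pack_params(p)
    y0 = (initial or initial_state(p)).as_array()
    dt = dt_ms / 1000.0
    for _attempt in range(3):
        states, n_beats, drift_edv, drift_sv, converged = _core.run_beats(
            pp, y0, dt, max_beats, min_beats, tol)
        if np.all(np.isfinite(states)):
            break
        dt *= 0.5
    else:
        raise ConvergenceError("integration diverged (non-finite state)", np.nan, np.nan)
    if not converged and raise_on_nonconvergence:
        raise ConvergenceError(
            f"no periodic steady state after {n_beats} beats "
            f"(EDV drift {drift_edv:.3g}, SV drift {drift_sv:.3g})",
            drift_edv, drift_sv)
    tr = _derive_traces(states, p)
    tr.n_beats = int(n_beats)
    tr.drift_edv = float(drift_edv)
    tr.drift_sv = float(drift_sv)
    tr.converged = bool(converged)
    tr.events = {
        "onset_atrial_ms": 0.0,
        "onset_earlier_ms": p.PR,
        "onset_delayed_ms": p.PR + p.delay_dT,
    }
    tr.events.update(_flow_events(tr.t_ms, tr.q_ao, "aortic"))
    tr.events.update(_flow_events(tr.t_ms, tr.q_av, "av"))
    return tr


def _mean(t_ms: np.ndarray, x: np.ndarray) -> float:
    return float(np.trapezoid(x, t_ms) / (t_ms[-1] - t_ms[0]))


def beat_metrics(
    tr: BeatTraces,
    p: CircuitParams,
    baseline_output: Optional[float] = None,
    compute_reverse_flow: bool = False,
) -> BeatMetrics:
    """Summarise a converged beat into clinical-style hemodynamic indices.

    Conventions: EDV is the maximal total ventricular volume of the beat
    (the volume at the earlier compartment's activation onset is also
    reported); ESV is the total volume at aortic valve closure; EDP is
    the outflow-compartment pressure at the earlier activation onset
    (QRS-onset convention); ESP is the peak outflow-compartment pressure.
    ``effective_ees`` is the single-beat time-varying-elastance surrogate
    ``max_t P_v(t) / (V_total(t) - V0_total)``.

    ``reverse_flow_pct`` (systolic delayed-to-earlier intercompartment
    backflow as % of a baseline per-beat output) requires
    ``baseline_output``; requesting it without one is an error.
    """
    t_ms = tr.t_ms
    t_s = t_ms / 1000.0
    v_tot = tr.v_total
    if "aortic_open_ms" not in tr.events or "aortic_close_ms" not in tr.events:
        raise ValueError("degenerate beat: aortic valve never opened (or never closed)")
    edv = float(v_tot.max())
    i_onset = int(np.argmin(np.abs(t_ms - p.PR)))
    i_close = int(np.argmin(np.abs(t_ms - tr.events["aortic_close_ms"])))
    esv = float(v_tot[i_close])
    if edv - esv < 1e-6 * edv:
        raise ValueError("degenerate beat: no volume excursion, EF undefined")
    p_out = tr.p_e if p.outflow_compartment == "earlier" else tr.p_d
    sv = float(np.trapezoid(tr.q_ao, t_s))
    co = sv * p.HR / 1000.0
    ci = co / p.BSA
    mean_cvp = _mean(t_ms, tr.p_cvp)
    mean_atr = _mean(t_ms, tr.p_atrium)
    mean_art = _mean(t_ms, tr.p_ao)
    v0_tot = p.ventricle_unit.V0 * N_VENTRICLE_UNITS
    with np.errstate(divide="ignore", invalid="ignore"):
        ees = float(np.nanmax(np.where(v_tot > v0_tot, p_out / (v_tot - v0_tot), np.nan)))
    if compute_reverse_flow:
        if baseline_output is None:
            raise ValueError("reverse_flow_pct requires baseline_output (ml per beat)")
        sys_mask = (t_ms >= p.PR) & (t_ms <= tr.events["aortic_close_ms"])
        backflow = np.clip(-tr.q_ic[sys_mask], 0.0, None)
        reverse_pct = float(np.trapezoid(backflow, t_s[sys_mask]) / baseline_output * 100.0)
    else:
        reverse_pct = np.nan
    return BeatMetrics(
        edv=edv,
        edv_at_onset=float(v_tot[i_onset]),
        esv=esv,
        ef=(edv - esv) / edv * 100.0,
        sv=sv, co=co, ci=ci,
        mean_cvp=mean_cvp, mean_atrial_p=mean_atr,
        esp=float(p_out.max()),
        p_at_aortic_closure=float(p_out[i_close]),
        edp=float(p_out[i_onset]),
        arterial_sys=float(tr.p_ao.max()),
        arterial_dia=float(tr.p_ao.min()),
        arterial_mean=mean_art,
        dpdt_max=float(np.max(np.gradient(p_out, t_s))),
        effective_ees=ees,
        pvri=(mean_cvp - mean_atr) / ci,
        svri=(mean_art - mean_cvp) / ci,
        reverse_flow_pct=reverse_pct,
        hr=p.HR, bsa=p.BSA,
    )


def count_reverse_flow_bursts(
    tr: BeatTraces, p: CircuitParams, threshold_frac: float = 0.05
) -> int:
    """Number of systolic delayed-to-earlier backflow episodes.

    A burst is a contiguous interval within systole (earlier activation
    onset to aortic valve closure) during which the reverse
    intercompartment flow exceeds ``threshold_frac`` times the beat's
    peak absolute intercompartment flow.  The swinging flow seen across a
    septal defect in dyssynchrony shows up as two such bursts, in early
    and late systole.
    """
    if "aortic_close_ms" not in tr.events:
        raise ValueError("beat has no aortic closure event")
    mask = (tr.t_ms >= p.PR) & (tr.t_ms <= tr.events["aortic_close_ms"])
    rev = np.clip(-tr.q_ic[mask], 0.0, None)
    thr = threshold_frac * float(np.max(np.abs(tr.q_ic)))
    above = rev > thr
    return int(np.sum(np.diff(above.astype(int)) == 1) + (1 if above[0] else 0))
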