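"""Closed-loop circulation: valve laws, conservation, steady-state behaviour."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st

import fontansim as fs
from fontansim import _core
from fontansim.chambers import compartment_parameters
from fontansim.circuit import (
    CircuitState,
    av_valve_pressure_drop,
    beat_metrics,
    derivatives,
    pack_params,
    initial_state,
    simulate_to_steady_state,
)


class TestAVValveLaw:
    def test_closed_form_example(self):
        assert av_valve_pressure_drop(300.0, 5.0, 1.06, 1333.0) == pytest.approx(
            1.431, abs=1e-3)

    def test_zero_flow_no_drop(self):
        assert av_valve_pressure_drop(0.0, 5.0) == 0.0

    @given(q=st.floats(1.0, 500.0))
    def test_quadratic_law(self, q):
        assert av_valve_pressure_drop(2 * q, 5.0) == pytest.approx(
            4 * av_valve_pressure_drop(q, 5.0), rel=1e-12)

    def test_negative_flow_rejected(self):
        with pytest.raises(ValueError):
            av_valve_pressure_drop(-1.0, 5.0)


def _passive_volume(pressure, p):
    return p.V0 + math.log(pressure / p.A + 1.0) / p.B


class TestDerivatives:
    def test_equilibrium_has_zero_volume_derivatives(self, params):
        """Equal node pressures with closed valves freeze all volumes."""
        pressure = 5.0
        pe = compartment_parameters(0.5, params.ventricle_unit)
        state = CircuitState(
            v_earlier=_passive_volume(pressure, pe),
            v_delayed=_passive_volume(pressure, pe),
            v_atrium=_passive_volume(pressure, params.atrium),
            v_sys_art=params.systemic.C_art * pressure,
            v_sys_ven=params.systemic.C_ven * pressure,
            v_pul_art=params.pulmonary.C_art * pressure,
            v_pul_ven=params.pulmonary.C_ven * pressure,
            q_av=0.0,
        )
        d = derivatives(state, 0.6, params)  # late diastole: all chambers relaxed
        for name in ("v_earlier", "v_delayed", "v_atrium", "v_sys_art",
                     "v_sys_ven", "v_pul_art", "v_pul_ven"):
            assert getattr(d, name) == pytest.approx(0.0, abs=1e-9)

    def test_node_pressure_from_compliance(self, params):
        """A 99-ml systemic arterial store at C = 1.1 sits at 90 mmHg."""
        state = initial_state(params)
        state.v_sys_art = 99.0
        d1 = derivatives(state, 0.6, params)
        # raise the downstream venous pressure by 1 mmHg: outflow drops by 1/R
        state2 = CircuitState(**{**vars(state)})
        state2.v_sys_ven += params.systemic.C_ven
        d2 = derivatives(state2, 0.6, params)
        assert (d1.v_sys_art - d2.v_sys_art) == pytest.approx(
            -1.0 / params.systemic.R_art, rel=1e-9)

    @given(
        vols=st.lists(st.floats(5.0, 400.0), min_size=7, max_size=7),
        q=st.floats(0.0, 300.0),
        t=st.floats(0.0, 0.75),
    )
    def test_volume_conservation_by_construction(self, params, vols, q, t):
        state = CircuitState(*vols, q_av=q)
        d = derivatives(state, t, params)
        parts = np.array([d.v_earlier, d.v_delayed, d.v_atrium, d.v_sys_art,
                          d.v_sys_ven, d.v_pul_art, d.v_pul_ven])
        assert abs(parts.sum()) < 1e-12 * max(1.0, np.abs(parts).max())

    def test_nonfinite_state_rejected(self, params):
        state = initial_state(params)
        state.v_atrium = math.nan
        with pytest.raises(ValueError):
            derivatives(state, 0.0, params)

    def test_compiled_kernel_matches_reference(self, params, rng):
        """The numba RHS and the Python reference give identical derivatives."""
        pp = pack_params(params)
        for _ in range(25):
            y = np.concatenate([rng.uniform(5.0, 400.0, 7), rng.uniform(0.0, 300.0, 1)])
            t = float(rng.uniform(0.0, 0.75))
            dy = np.empty(8)
            _core.rhs(t, y, pp, dy)
            d = derivatives(CircuitState.from_array(y), t, params)
            np.testing.assert_allclose(dy, d.as_array(), rtol=1e-10, atol=1e-10)


class TestSteadyState:
    def test_baseline_converges_periodically(self, baseline):
        params, tr, m = baseline
        assert tr.converged
        assert tr.drift_edv < 1e-5 and tr.drift_sv < 1e-5

    def test_total_stressed_volume_conserved(self, baseline):
        params, tr, m = baseline
        total = (tr.v_e + tr.v_d + tr.v_atrium
                 + tr.p_art * params.systemic.C_art
                 + tr.p_sys_ven * params.systemic.C_ven
                 + tr.p_pa * params.pulmonary.C_art
                 + tr.p_pv * params.pulmonary.C_ven)
        np.testing.assert_allclose(total, params.total_stressed_volume, rtol=1e-9)

    def test_valves_are_diodes(self, baseline):
        _, tr, _ = baseline
        assert np.all(tr.q_ao >= 0.0)
        assert np.all(tr.q_av >= 0.0)

    def test_zero_delay_pressure_symmetry(self, params):
        """With dT = 0 the two compartments track each other closely for any split."""
        for fraction in (0.25, 0.75):
            tr = simulate_to_steady_state(params.replace(delayed_fraction=fraction))
            assert np.max(np.abs(tr.p_e - tr.p_d)) < 4.0  # ~ Q_ic * R_ic bound

    def test_zero_delay_baseline_is_fraction_invariant(self, params, baseline):
        _, _, m0 = baseline
        for fraction in (0.05, 0.95):
            tr = simulate_to_steady_state(params.replace(delayed_fraction=fraction))
            m = beat_metrics(tr, params.replace(delayed_fraction=fraction))
            assert m.co == pytest.approx(m0.co, rel=0.03)
            assert m.edv == pytest.approx(m0.edv, rel=0.03)

    def test_large_delayed_fraction_mimics_av_delay(self, params):
        """A 95% delayed ventricle at dT behaves like a whole ventricle with a
        prolonged atrioventricular delay."""
        dT = 60.0
        tr_a = simulate_to_steady_state(
            params.replace(delayed_fraction=0.95, delay_dT=dT))
        m_a = beat_metrics(tr_a, params.replace(delayed_fraction=0.95, delay_dT=dT))
        p_b = params.replace(PR=params.PR + dT, delay_dT=0.0)
        tr_b = simulate_to_steady_state(p_b)
        m_b = beat_metrics(tr_b, p_b)
        assert m_a.co == pytest.approx(m_b.co, rel=0.05)
        assert m_a.edv == pytest.approx(m_b.edv, rel=0.05)

    def test_nonconvergence_raises_with_drift(self, params):
        with pytest.raises(fs.ConvergenceError) as err:
            simulate_to_steady_state(params, max_beats=3, min_beats=2, tol=1e-12)
        assert math.isfinite(err.value.drift_edv)


class TestBeatMetrics:
    def test_degenerate_trace_rejected(self, baseline):
        params, tr, _ = baseline
        import copy
        flat = copy.deepcopy(tr)
        flat.events.pop("aortic_open_ms", None)
        with pytest.raises(ValueError):
            beat_metrics(flat, params)

    def test_reverse_flow_requires_baseline(self, baseline):
        params, tr, _ = baseline
        with pytest.raises(ValueError):
            beat_metrics(tr, params, compute_reverse_flow=True)

    def test_ef_is_consistent_with_volumes(self, baseline):
        _, tr, m = baseline
        assert 0.0 < m.ef < 100.0
        assert m.edv > m.esv
        assert m.ef == pytest.approx((m.edv - m.esv) / m.edv * 100.0)

    def test_resistance_indices_follow_from_pressures(self, baseline):
        _, _, m = baseline
        assert m.pvri == pytest.approx((m.mean_cvp - m.mean_atrial_p) / m.ci)
        assert m.svri == pytest.approx((m.arterial_mean - m.mean_cvp) / m.ci)
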