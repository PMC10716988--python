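"""Hemisphere geometry, strain synthesis, and discoordination indices."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from fontansim.strain import (
    StrainTraces,
    area_ratio_from_length_ratio,
    count_shortening_minima,
    hemiglobal_strains,
    hemisphere_radius,
    length_ratio_from_area_ratio,
    r_strains,
    segment_lengths,
    time_to_peak_difference,
)


class TestRatioConversions:
    @pytest.mark.parametrize("lr, ar", [(0.0, 0.0), (0.5, 0.5), (1.0, 1.0),
                                        (2.0 / 3.0, 0.75)])
    def test_known_values(self, lr, ar):
        assert area_ratio_from_length_ratio(lr) == pytest.approx(ar, abs=1e-12)
        assert length_ratio_from_area_ratio(ar) == pytest.approx(lr, abs=1e-12)

    @given(ar=st.floats(0.0, 1.0))
    def test_round_trip_machine_precision(self, ar):
        lr = length_ratio_from_area_ratio(ar)
        assert area_ratio_from_length_ratio(lr) == pytest.approx(ar, abs=1e-12)

    def test_monotone(self):
        lr = np.linspace(0.0, 1.0, 501)
        assert np.all(np.diff(area_ratio_from_length_ratio(lr)) > 0)

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            area_ratio_from_length_ratio(1.2)
        with pytest.raises(ValueError):
            length_ratio_from_area_ratio(-0.1)


class TestHemisphereRadius:
    def test_unit_radius(self):
        assert hemisphere_radius(2.0 * np.pi / 3.0) == pytest.approx(1.0, abs=1e-12)

    def test_baseline_edv(self):
        assert hemisphere_radius(102.0) == pytest.approx(3.652, abs=2e-3)

    @given(v=st.floats(1.0, 500.0))
    def test_cube_root_scaling(self, v):
        assert hemisphere_radius(8.0 * v) == pytest.approx(2.0 * hemisphere_radius(v))

    def test_positive_volume_required(self):
        with pytest.raises(ValueError):
            hemisphere_radius(0.0)


class TestHemiglobalStrains:
    def test_uniform_contraction_follows_cube_root(self):
        """Scaling both volumes by k(t) gives strain 100 (k^(1/3) - 1) on both sides."""
        t = np.linspace(0.0, 750.0, 751)
        k = 1.0 - 0.5 * np.sin(np.pi * t / 750.0) ** 2   # dips to 0.5
        v_e, v_d = 40.0 * k, 60.0 * k
        st_tr = hemiglobal_strains(t, v_e, v_d, ed_time_ms=0.0)
        expected = 100.0 * (k ** (1.0 / 3.0) - 1.0)
        np.testing.assert_allclose(st_tr.earlier, expected, atol=1e-9)
        np.testing.assert_allclose(st_tr.delayed, expected, atol=1e-9)
        assert st_tr.earlier[np.argmin(k)] == pytest.approx(-20.63, abs=0.01)

    def test_constant_volumes_zero_strain(self):
        t = np.linspace(0.0, 500.0, 101)
        st_tr = hemiglobal_strains(t, np.full_like(t, 30.0), np.full_like(t, 70.0))
        np.testing.assert_allclose(st_tr.earlier, 0.0, atol=1e-12)
        np.testing.assert_allclose(st_tr.delayed, 0.0, atol=1e-12)

    def test_zero_at_end_diastolic_reference(self):
        t = np.linspace(0.0, 750.0, 751)
        v_e = 40.0 + 5.0 * np.sin(t / 80.0)
        v_d = 60.0 - 8.0 * np.sin(t / 95.0)
        st_tr = hemiglobal_strains(t, v_e, v_d, ed_time_ms=100.0)
        i_ed = 100
        assert st_tr.earlier[i_ed] == 0.0
        assert st_tr.delayed[i_ed] == 0.0

    def test_proportional_compartments_are_symmetric(self):
        """When both compartments scale together, earlier and delayed agree."""
        t = np.linspace(0.0, 750.0, 751)
        k = 1.0 - 0.4 * np.sin(np.pi * t / 750.0) ** 2
        st_tr = hemiglobal_strains(t, 50.0 * k, 50.0 * k)
        np.testing.assert_allclose(st_tr.earlier, st_tr.delayed, atol=1e-9)

    def test_simulated_zero_delay_near_symmetric_in_systole(self, baseline):
        """With zero delay the two walls contract together; the small residual
        asymmetry (AV inflow transits the earlier compartment) is diastolic."""
        params, tr, _ = baseline
        st_tr = hemiglobal_strains(tr.t_ms, tr.v_e, tr.v_d, tr.events)
        systole = (tr.t_ms >= params.PR) & (tr.t_ms <= tr.events["aortic_close_ms"])
        assert np.max(np.abs(st_tr.earlier - st_tr.delayed)[systole]) < 1.5
        r_e = r_strains(st_tr.t_ms, st_tr.earlier, tr.events)
        r_d = r_strains(st_tr.t_ms, st_tr.delayed, tr.events)
        assert r_e == pytest.approx(r_d, abs=0.02)

    def test_nonpositive_volume_rejected(self):
        t = np.linspace(0.0, 10.0, 11)
        with pytest.raises(ValueError):
            hemiglobal_strains(t, np.zeros_like(t) - 1.0, np.ones_like(t))

    def test_segment_lengths_sum_to_outline(self):
        rng = np.random.default_rng(7)
        v_e = rng.uniform(10.0, 60.0, 200)
        v_d = rng.uniform(10.0, 60.0, 200)
        lengths = segment_lengths(v_e, v_d, i_ed=0)
        outline = np.pi * hemisphere_radius(v_e + v_d)
        np.testing.assert_allclose(lengths.sum(axis=1), outline, rtol=1e-12)


EVENTS = {"onset_earlier_ms": 100.0, "aortic_open_ms": 200.0, "aortic_close_ms": 400.0}


def _trace_with_minima(ivc_min, ej_min):
    """Piecewise-linear strain with interior minima ivc_min (150 ms, during
    isovolumic contraction) and ej_min (300 ms, during ejection)."""
    t = np.linspace(0.0, 500.0, 501)
    strain = np.interp(t, [0.0, 100.0, 150.0, 200.0, 300.0, 400.0, 500.0],
                       [0.0, 0.0, ivc_min, ivc_min / 2, ej_min, 0.0, 0.0])
    return t, strain


class TestRStrains:
    @pytest.mark.parametrize("ivc, ej, expected", [
        (-15.0, -15.0, 1.0),
        (-20.0, -10.0, 1.125),       # rebound stretch: 90/80
        (-10.0, -20.0, 80.0 / 90.0),  # deeper ejection shortening
    ])
    def test_arithmetic(self, ivc, ej, expected):
        t, strain = _trace_with_minima(ivc, ej)
        assert r_strains(t, strain, EVENTS) == pytest.approx(expected, rel=1e-9)

    def test_missing_events(self):
        t, strain = _trace_with_minima(-10.0, -10.0)
        with pytest.raises(ValueError):
            r_strains(t, strain, {"onset_earlier_ms": 100.0})

    @given(depth=st.floats(1.0, 40.0), hold=st.floats(0.0, 0.9))
    def test_monotone_shortening_never_exceeds_one(self, depth, hold):
        """A wall that shortens monotonically then holds has no rebound (R <= 1)."""
        t = np.linspace(0.0, 500.0, 501)
        strain = -depth * np.clip(t / (100.0 + 300.0 * hold), 0.0, 1.0)
        assert r_strains(t, strain, EVENTS) <= 1.0 + 1e-12


class TestTimeToPeak:
    def test_identical_traces(self):
        t = np.linspace(0.0, 750.0, 751)
        s = -10.0 * np.sin(np.pi * t / 750.0)
        st_tr = StrainTraces(t_ms=t, earlier=s, delayed=s.copy())
        assert time_to_peak_difference(st_tr) == 0.0

    def test_shifted_trace(self):
        t = np.linspace(0.0, 750.0, 751)
        s = -10.0 * np.exp(-((t - 300.0) / 80.0) ** 2)
        shifted = -10.0 * np.exp(-((t - 360.0) / 80.0) ** 2)
        st_tr = StrainTraces(t_ms=t, earlier=s, delayed=shifted)
        assert time_to_peak_difference(st_tr) == pytest.approx(60.0, abs=1.0)

    def test_first_global_minimum_wins(self):
        """Scan oracle: with two equal minima the earlier sample is the peak."""
        t = np.arange(0.0, 500.0)
        s = np.zeros_like(t)
        s[[100, 300]] = -20.0
        expected = t[int(min(np.flatnonzero(s == s.min())))]
        st_tr = StrainTraces(t_ms=t, earlier=s, delayed=np.where(t == 300, -20.0, 0.0))
        assert time_to_peak_difference(st_tr) == pytest.approx(300.0 - expected)


def test_count_shortening_minima_on_synthetic_shapes():
    t = np.linspace(0.0, 500.0, 501)
    mono = -20.0 * np.sin(np.pi * np.clip(t, 0, 400) / 400.0)
    assert count_shortening_minima(t, mono, 0.0, 500.0) == 1
    double = mono + 8.0 * np.exp(-((t - 250.0) / 40.0) ** 2)
    assert count_shortening_minima(t, double, 0.0, 500.0) == 2
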