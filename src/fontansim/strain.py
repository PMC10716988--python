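"""Hemispherical strain synthesis and discoordination indices.

The ventricle is a hemisphere of volume ``V = (2/3) pi r^3``.  On an
apical-view coronal cut through the vertex the wall outline is a
semicircle of length ``pi r``.  A wall region occupying a length
fraction ``LR`` of the base-to-base outline occupies the area (and,
under identical curvature, volume) fraction

    AR = (1 - cos(pi LR)) / 2

of the hemisphere; the delayed-wall area ratio reported in percent at
clinical interfaces is this quantity.  The same identity applied
instantaneously maps simulated compartment volumes onto arcs of the
outline, from which seven-segment longitudinal strains are synthesised
the way speckle-tracking echocardiography measures them: the outline is
divided into seven equal material segments at end-diastole, each
material point keeps its relative position within its compartment's
arc, and a "hemiglobal" strain averages the three basal segments of one
side, excluding the apical cap.

The systolic-rebound-stretch index is
``R_strains = (100 + Strain_ejection) / (100 + Strain_isovolumic)``
where each term is the minimum (most negative) strain within the
isovolumic-contraction and ejection windows; values above 1 flag an
early-activated wall that shortens before aortic opening and is then
stretched back during ejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "StrainTraces",
    "area_ratio_from_length_ratio",
    "length_ratio_from_area_ratio",
    "hemisphere_radius",
    "hemiglobal_strains",
    "segment_lengths",
    "r_strains",
    "time_to_peak_difference",
    "count_shortening_minima",
]

N_SEGMENTS = 7
HEMIGLOBAL_SEGMENTS = 3  # basal segments per side; segment 4 is the apical cap


def area_ratio_from_length_ratio(LR):
    """Area (volume) fraction of a wall occupying outline fraction ``LR``."""
    LR = np.asarray(LR, dtype=float)
    if np.any((LR < 0) | (LR > 1)):
        raise ValueError("LR must be in [0, 1]")
    out = 0.5 * (1.0 - np.cos(np.pi * LR))
    return float(out) if out.ndim == 0 else out


def length_ratio_from_area_ratio(AR):
    """Inverse mapping: outline fraction of a wall with area fraction ``AR``."""
    AR = np.asarray(AR, dtype=float)
    if np.any((AR < 0) | (AR > 1)):
        raise ValueError("AR must be in [0, 1]")
    out = np.arccos(1.0 - 2.0 * AR) / np.pi
    return float(out) if out.ndim == 0 else out


def hemisphere_radius(V):
    """Radius (cm) of a hemisphere of volume ``V`` (ml): ``(3V / 2 pi)^(1/3)``."""
    V = np.asarray(V, dtype=float)
    if np.any(V <= 0):
        raise ValueError("volume must be positive")
    out = (3.0 * V / (2.0 * np.pi)) ** (1.0 / 3.0)
    return float(out) if out.ndim == 0 else out


@dataclass
class StrainTraces:
    """Two hemiglobal longitudinal strain time series (%, 0 at end-diastole)."""

    t_ms: np.ndarray
    earlier: np.ndarray
    delayed: np.ndarray
    events: dict = field(default_factory=dict)


def _material_interval_length(x1, x2, b0, arc_e, arc_d):
    """Current length of the end-diastolic outline interval [x1, x2].

    ``x1``/``x2`` are material positions as fractions of the end-diastolic
    outline measured from the earlier base; ``b0`` is the compartment
    boundary at end-diastole.  Each sub-interval stretches uniformly with
    its compartment's arc (``arc_e``/``arc_d``, current lengths in cm);
    an interval straddling the boundary is split there.
    """
    in_e = max(0.0, min(x2, b0) - min(x1, b0))
    in_d = max(0.0, x2 - max(x1, b0))
    len_e = in_e / b0 * arc_e if b0 > 0 else 0.0
    len_d = in_d / (1.0 - b0) * arc_d if b0 < 1 else 0.0
    return len_e + len_d


def segment_lengths(v_e: np.ndarray, v_d: np.ndarray, i_ed: int) -> np.ndarray:
    """Current lengths (cm) of the 7 material outline segments, per sample.

    Segments are equal sevenths of the outline at the end-diastolic sample
    ``i_ed``, numbered from the earlier base.  Their lengths always sum to
    the instantaneous outline length ``pi r(t)``.
    """
    v_e = np.asarray(v_e, float)
    v_d = np.asarray(v_d, float)
    if np.any(v_e <= 0) or np.any(v_d <= 0):
        raise ValueError("compartment volumes must be positive")
    v_tot = v_e + v_d
    r = hemisphere_radius(v_tot)
    outline = np.pi * r
    lr_e = length_ratio_from_area_ratio(v_e / v_tot)
    arc_e = lr_e * outline
    arc_d = outline - arc_e
    b0 = float(lr_e[i_ed])
    bounds = np.linspace(0.0, 1.0, N_SEGMENTS + 1)
    lengths = np.empty((len(v_e), N_SEGMENTS))
    for k in range(N_SEGMENTS):
        x1, x2 = bounds[k], bounds[k + 1]
        in_e = max(0.0, min(x2, b0) - min(x1, b0))
        in_d = max(0.0, x2 - max(x1, b0))
        le = in_e / b0 * arc_e if b0 > 0 else 0.0
        ld = in_d / (1.0 - b0) * arc_d if b0 < 1 else 0.0
        lengths[:, k] = le + ld
    return lengths


def hemiglobal_strains(
    t_ms: np.ndarray,
    v_e: np.ndarray,
    v_d: np.ndarray,
    events: dict | None = None,
    ed_time_ms: float | None = None,
) -> StrainTraces:
    """Synthesise the two hemiglobal strains from compartment volume traces.

    The end-diastolic reference sample is ``ed_time_ms`` if given, else
    the earlier activation onset from ``events`` (key
    ``onset_earlier_ms``), else the first sample.  Each hemiglobal strain
    is the relative length change of the three basal material segments on
    that side (apical cap excluded), in percent, 0 at the reference.
    """
    t_ms = np.asarray(t_ms, float)
    events = dict(events or {})
    if ed_time_ms is None:
        ed_time_ms = events.get("onset_earlier_ms", t_ms[0])
    i_ed = int(np.argmin(np.abs(t_ms - ed_time_ms)))
    lengths = segment_lengths(v_e, v_d, i_ed)
    k = HEMIGLOBAL_SEGMENTS
    len_e = lengths[:, :k].sum(axis=1)
    len_d = lengths[:, -k:].sum(axis=1)
    strain_e = 100.0 * (len_e / len_e[i_ed] - 1.0)
    strain_d = 100.0 * (len_d / len_d[i_ed] - 1.0)
    events.setdefault("ed_ms", float(t_ms[i_ed]))
    return StrainTraces(t_ms=t_ms, earlier=strain_e, delayed=strain_d, events=events)


def _window_min(t_ms, strain, t0, t1):
    mask = (t_ms >= t0) & (t_ms <= t1)
    if not mask.any():
        raise ValueError(f"empty strain window [{t0}, {t1}] ms")
    return float(np.min(strain[mask]))


def r_strains(
    t_ms: np.ndarray,
    strain: np.ndarray,
    events: dict,
    window_start: str = "onset",
) -> float:
    """Systolic rebound-stretch ratio of one strain trace.

    ``Strain_isovolumic`` is the minimum strain between the activation
    onset (or, with ``window_start='qrs'``, the atrial-lead QRS proxy
    ``onset_atrial_ms``) and aortic valve opening; ``Strain_ejection``
    the minimum between aortic opening and closure.  Returns
    ``(100 + Strain_ejection) / (100 + Strain_isovolumic)``.
    """
    t_ms = np.asarray(t_ms, float)
    strain = np.asarray(strain, float)
    start_key = "onset_earlier_ms" if window_start == "onset" else "onset_atrial_ms"
    for key in (start_key, "aortic_open_ms", "aortic_close_ms"):
        if key not in events:
            raise ValueError(f"missing event {key!r}")
    s_ivc = _window_min(t_ms, strain, events[start_key], events["aortic_open_ms"])
    s_ej = _window_min(t_ms, strain, events["aortic_open_ms"], events["aortic_close_ms"])
    return (100.0 + s_ej) / (100.0 + s_ivc)


def time_to_peak_difference(st: StrainTraces) -> float:
    """Delay (ms) of the delayed trace's peak shortening behind the earlier one.

    Peak shortening is the global minimum of each trace; on ties the
    first occurrence wins.
    """
    i_e = int(np.argmin(st.earlier))
    i_d = int(np.argmin(st.delayed))
    return float(st.t_ms[i_d] - st.t_ms[i_e])


def count_shortening_minima(
    t_ms: np.ndarray,
    strain: np.ndarray,
    t0: float,
    t1: float,
    prominence: float = 0.1,
) -> int:
    """Number of distinct shortening troughs of a strain trace in [t0, t1] ms.

    Local minima of the strain (peaks of its negative) with at least
    ``prominence`` percentage points of prominence (the default rejects
    flat-minimum jitter while keeping the shallow mid-systolic rebound
    that separates the two troughs of a discoordinated wall).  One trough is a
    monophasic contraction; two signal the early-shortening /
    rebound-stretch / late-shortening pattern of the early-activated
    wall under a large activation delay.
    """
    from scipy.signal import find_peaks

    t_ms = np.asarray(t_ms, float)
    mask = (t_ms >= t0) & (t_ms <= t1)
    peaks, _ = find_peaks(-np.asarray(strain, float)[mask], prominence=prominence)
    return int(len(peaks))
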