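"""Activation-delay x delayed-fraction sweep and cross-condition statistics.

The default experiment crosses 19 activation delays (0-90 ms in 5-ms
steps) with 19 delayed-compartment volume fractions (5-95% in 5% steps),
361 steady-state runs in total.  For every condition the per-beat
hemodynamics, the strain-derived discoordination indices and the changes
of cardiac output, contractility surrogate and dP/dt-max *relative to
the same fraction's zero-delay baseline* are tabulated.  Rank
correlations across the grid identify which discoordination marker best
predicts the loss of contractility.
"""

from __future__ import annotations

import logging
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .circuit import beat_metrics, simulate_to_steady_state, ConvergenceError
from .config import CircuitParams
from .strain import hemiglobal_strains, r_strains, time_to_peak_difference

__all__ = [
    "default_dT_grid",
    "default_fraction_grid",
    "run_condition",
    "run_grid",
    "most_vulnerable_fraction",
    "spearman_rho",
    "correlate_predictors",
    "PREDICTORS",
]

log = logging.getLogger(__name__)

#: candidate predictors of the contractility change, as table columns
PREDICTORS = ("d_dpdt_pct", "reverse_flow_pct", "ttp_diff_ms", "r_strains_earlier")


def default_dT_grid() -> np.ndarray:
    """Activation delays 0..90 ms in 5-ms steps (19 values)."""
    return np.arange(0.0, 95.0, 5.0)


def default_fraction_grid() -> np.ndarray:
    """Delayed-compartment fractions 0.05..0.95 in 0.05 steps (19 values)."""
    return np.round(np.arange(1, 20) * 0.05, 2)


def run_condition(p: CircuitParams, dT_ms: float, fraction: float, **sim_kwargs):
    """One steady-state run; returns ``(traces, strains)`` for the condition."""
    cond = p.replace(delay_dT=float(dT_ms), delayed_fraction=float(fraction))
    tr = simulate_to_steady_state(cond, **sim_kwargs)
    st = hemiglobal_strains(tr.t_ms, tr.v_e, tr.v_d, tr.events)
    return cond, tr, st


def _row(p, dT_ms, fraction, tr, st, baseline_sv) -> dict:
    cond = p.replace(delay_dT=float(dT_ms), delayed_fraction=float(fraction))
    m = beat_metrics(tr, cond, baseline_output=baseline_sv,
                     compute_reverse_flow=baseline_sv is not None)
    row = {
        "dT_ms": float(dT_ms), "fraction": float(fraction),
        "edv": m.edv, "esv": m.esv, "ef": m.ef, "sv": m.sv, "co": m.co, "ci": m.ci,
        "mean_cvp": m.mean_cvp, "mean_atrial_p": m.mean_atrial_p,
        "esp": m.esp, "edp": m.edp, "arterial_mean": m.arterial_mean,
        "dpdt_max": m.dpdt_max, "ees": m.effective_ees,
        "reverse_flow_pct": m.reverse_flow_pct,
        "converged": tr.converged, "n_beats": tr.n_beats,
    }
    row["r_strains_earlier"] = r_strains(st.t_ms, st.earlier, tr.events)
    row["r_strains_delayed"] = r_strains(st.t_ms, st.delayed, tr.events)
    row["ttp_diff_ms"] = time_to_peak_difference(st)
    return row


def run_grid(
    p: CircuitParams,
    dT_list: Optional[Iterable[float]] = None,
    fraction_list: Optional[Iterable[float]] = None,
    **sim_kwargs,
) -> pd.DataFrame:
    """Run the full delay-by-fraction grid and tabulate per-condition results.

    Every fraction's zero-delay condition is simulated (whether or not 0
    is in ``dT_list``) and serves as that fraction's baseline for the
    relative-change columns ``d_co_pct``, ``d_ees_pct`` and
    ``d_dpdt_pct`` and for normalising the systolic reverse flow.
    Non-convergent conditions are flagged (``converged=False``) and the
    sweep continues.  Rows are sorted by (dT_ms, fraction); results do
    not depend on execution order.
    """
    dTs = np.asarray(list(default_dT_grid() if dT_list is None else dT_list), float)
    fracs = np.asarray(list(default_fraction_grid() if fraction_list is None else fraction_list), float)
    if dTs.size == 0 or fracs.size == 0:
        raise ValueError("dT_list and fraction_list must be non-empty")
    rows = []
    for fraction in fracs:
        try:
            _, tr0, st0 = run_condition(p, 0.0, fraction, **sim_kwargs)
        except ConvergenceError as err:
            log.warning("baseline (dT=0, fraction=%.2f) failed: %s", fraction, err)
            for dT in dTs:
                rows.append({"dT_ms": float(dT), "fraction": float(fraction),
                             "converged": False})
            continue
        m0 = beat_metrics(tr0, p.replace(delayed_fraction=float(fraction)))
        base_row = _row(p, 0.0, fraction, tr0, st0, m0.sv)
        for dT in dTs:
            if dT == 0.0:
                row = dict(base_row)
            else:
                try:
                    _, tr, st = run_condition(p, dT, fraction, **sim_kwargs)
                    row = _row(p, dT, fraction, tr, st, m0.sv)
                except ConvergenceError as err:
                    log.warning("condition (dT=%g, fraction=%.2f) failed: %s",
                                dT, fraction, err)
                    rows.append({"dT_ms": float(dT), "fraction": float(fraction),
                                 "converged": False})
                    continue
            row["d_co_pct"] = 100.0 * (row["co"] - base_row["co"]) / base_row["co"]
            row["d_ees_pct"] = 100.0 * (row["ees"] - base_row["ees"]) / base_row["ees"]
            row["d_dpdt_pct"] = 100.0 * (row["dpdt_max"] - base_row["dpdt_max"]) / base_row["dpdt_max"]
            rows.append(row)
            log.debug("dT=%g fraction=%.2f: dCO=%.2f%%", dT, fraction, row["d_co_pct"])
    tab = pd.DataFrame(rows).sort_values(["dT_ms", "fraction"], kind="mergesort")
    return tab.reset_index(drop=True)


def most_vulnerable_fraction(
    tab: pd.DataFrame, dT_ms: float, metric: str = "d_co_pct"
) -> float:
    """Fraction with the largest reduction of ``metric`` at the given delay.

    Returns the delayed-compartment fraction minimising the (signed)
    relative-change metric at ``dT_ms``; exact ties break toward the
    smaller fraction.
    """
    sub = tab[np.isclose(tab["dT_ms"], dT_ms)]
    if sub.empty:
        raise ValueError(f"dT={dT_ms} ms not present in the sweep table")
    sub = sub.sort_values("fraction")
    values = sub[metric].to_numpy()
    return float(sub["fraction"].to_numpy()[int(np.argmin(values))])


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman rank correlation with midrank tie handling."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("x and y must have equal length >= 3")
    return float(stats.spearmanr(x, y).statistic)


def correlate_predictors(
    tab: pd.DataFrame, response: str = "d_ees_pct",
    predictors: Sequence[str] = PREDICTORS,
) -> pd.DataFrame:
    """Spearman rho of each candidate discoordination marker vs ``response``."""
    sub = tab[tab["converged"]] if "converged" in tab.columns else tab
    out = [{"predictor": name, "rho": spearman_rho(sub[name], sub[response])}
           for name in predictors]
    df = pd.DataFrame(out)
    df["abs_rho"] = df["rho"].abs()
    return df.sort_values("abs_rho", ascending=False).reset_index(drop=True)
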