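"""Clinical indices and the response-surface analysis of a patient cohort.

A cohort is a DataFrame with one row per patient and (at least) the
columns ``QRSZ`` (QRS-duration Z-score), ``AR_delayed`` (delayed-wall
area ratio, percent), ``BNP`` (pg/ml) and ``estEes`` (mmHg/ml/m^2).
``estEes`` is the load-surrogate contractility index: dicrotic-notch
aortic pressure divided by the indexed end-systolic volume.

The combined effect of the electrical delay and the delayed-wall ratio
on a response (log10 BNP or estEes) is modelled by a second-order
polynomial response surface in the five terms

    QRSZ,  AR,  (QRSZ - c1)^2,  (AR - c2)^2,  (QRSZ - c1)(AR - c2)

with the centering constants c1, c2 equal to the cohort means, fitted by
ordinary least squares.  Standardized coefficients (beta) are obtained
by z-scoring the response and each constructed term.  An inverse-U
response in AR has a negative (AR - c2)^2 coefficient; the AR at which
the response is extremal for a fixed QRSZ is the vertex of that
quadratic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "TERM_NAMES",
    "SurfaceFit",
    "ExtremumResult",
    "est_ees",
    "validate_cohort",
    "fit_response_surface",
    "extremum_ar_at",
]

TERM_NAMES = ("QRSZ", "AR", "QRSZ_sq", "AR_sq", "cross")

REQUIRED_COLUMNS = ("QRSZ", "AR_delayed", "BNP", "estEes")


def est_ees(AP_dic, ESVi):
    """End-systolic elastance surrogate: dicrotic-notch pressure / ESVi.

    ``AP_dic`` in mmHg, ``ESVi`` in ml/m^2; the result is in
    mmHg/ml/m^2 (equivalently mmHg ml^-1 m^2).
    """
    AP_dic = np.asarray(AP_dic, dtype=float)
    ESVi = np.asarray(ESVi, dtype=float)
    if np.any(ESVi <= 0):
        raise ValueError("ESVi must be positive")
    out = AP_dic / ESVi
    return float(out) if out.ndim == 0 else out


def validate_cohort(cohort: pd.DataFrame) -> None:
    """Check the patient-record invariants of a cohort table."""
    for col in REQUIRED_COLUMNS:
        if col not in cohort.columns:
            raise ValueError(f"cohort is missing column {col!r}")
    if (cohort["QRSZ"] < 2).any():
        raise ValueError("QRSZ below the inclusion threshold of 2")
    if ((cohort["AR_delayed"] <= 0) | (cohort["AR_delayed"] >= 100)).any():
        raise ValueError("AR_delayed must lie strictly between 0 and 100 percent")
    if (cohort["BNP"] <= 0).any():
        raise ValueError("BNP must be positive")


@dataclass
class SurfaceFit:
    """Fitted second-order response surface."""

    response: str
    coef: dict            # raw coefficients incl. "const", original units
    beta: dict            # standardized coefficients per term
    pvalues: dict         # per-term p-values (classical OLS t-tests)
    c1: float             # QRSZ centering constant (sample mean)
    c2: float             # AR centering constant (sample mean, percent)
    r2: float
    ar_range: tuple       # observed AR range of the fitted cohort
    n: int


@dataclass
class ExtremumResult:
    ar: float
    clipped: bool


def _design(qrsz, ar, c1, c2, standardize_first=False):
    if standardize_first:
        qrsz = (qrsz - qrsz.mean()) / qrsz.std(ddof=1)
        ar = (ar - ar.mean()) / ar.std(ddof=1)
        c1, c2 = 0.0, 0.0
    terms = np.column_stack([
        qrsz, ar, (qrsz - c1) ** 2, (ar - c2) ** 2, (qrsz - c1) * (ar - c2),
    ])
    return terms, c1, c2


def fit_response_surface(
    cohort: pd.DataFrame,
    response: str = "log10BNP",
    standardize_first: bool = False,
) -> SurfaceFit:
    """Fit the five-term second-order polynomial surface by OLS.

    Parameters
    ----------
    cohort : DataFrame
        Patient table; must satisfy :func:`validate_cohort` columns and
        contain at least 10 complete rows.
    response : {'log10BNP', 'estEes'}
        ``log10BNP`` fits the base-10 logarithm of the BNP column.
    standardize_first : bool
        If True, z-score QRSZ and AR *before* constructing the quadratic
        and cross terms (an alternative reading of "standardized
        coefficients"); default constructs the terms on the original
        scales and z-scores each constructed term.
    """
    validate_cohort(cohort)
    if response == "log10BNP":
        y = np.log10(cohort["BNP"].to_numpy(float))
    elif response == "estEes":
        y = cohort["estEes"].to_numpy(float)
    else:
        raise ValueError(f"unknown response {response!r}")
    qrsz = cohort["QRSZ"].to_numpy(float)
    ar = cohort["AR_delayed"].to_numpy(float)
    mask = np.isfinite(y) & np.isfinite(qrsz) & np.isfinite(ar)
    if mask.sum() < 10:
        raise ValueError(f"need at least 10 complete records, have {mask.sum()}")
    y, qrsz, ar = y[mask], qrsz[mask], ar[mask]
    c1, c2 = float(qrsz.mean()), float(ar.mean())
    terms, c1, c2 = _design(qrsz, ar, c1, c2, standardize_first)

    X = sm.add_constant(terms, has_constant="add")
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        sds = terms.std(axis=0)
        bad = [TERM_NAMES[i] for i in range(5) if sds[i] < 1e-12]
        raise ValueError(
            "rank-deficient design matrix; degenerate/collinear terms: "
            + (", ".join(bad) if bad else "(linear dependence among terms)"))
    res = sm.OLS(y, X).fit()

    # standardized coefficients: z-score response and each constructed term
    y_sd = y.std(ddof=1)
    if y_sd < 1e-12:
        beta = {name: 0.0 for name in TERM_NAMES}
    else:
        zt = (terms - terms.mean(axis=0)) / terms.std(axis=0, ddof=1)
        zres = sm.OLS((y - y.mean()) / y_sd, sm.add_constant(zt)).fit()
        beta = dict(zip(TERM_NAMES, zres.params[1:]))

    coef = {"const": res.params[0], **dict(zip(TERM_NAMES, res.params[1:]))}
    pvalues = dict(zip(TERM_NAMES, res.pvalues[1:]))
    return SurfaceFit(
        response=response, coef=coef, beta=beta, pvalues=pvalues,
        c1=c1, c2=c2, r2=float(res.rsquared) if y_sd > 1e-12 else 0.0,
        ar_range=(float(ar.min()), float(ar.max())), n=int(mask.sum()),
    )


def extremum_ar_at(fit: SurfaceFit, qrsz: float) -> ExtremumResult:
    """AR (%) at which the fitted surface is extremal for a fixed QRSZ.

    Vertex of the fitted quadratic in AR:
    ``AR* = c2 - (b_AR + b_cross (qrsz - c1)) / (2 b_AR_sq)``.
    The result is clipped to the observed AR range of the fitted cohort;
    ``clipped`` flags when the analytic vertex fell outside it.
    """
    b_ar2 = fit.coef["AR_sq"]
    if b_ar2 == 0:
        raise ValueError("quadratic AR coefficient is zero; no extremum")
    ar_star = fit.c2 - (fit.coef["AR"] + fit.coef["cross"] * (qrsz - fit.c1)) / (2.0 * b_ar2)
    lo, hi = fit.ar_range
    clipped = not (lo <= ar_star <= hi)
    return ExtremumResult(ar=float(np.clip(ar_star, lo, hi)), clipped=clipped)
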