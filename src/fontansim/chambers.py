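"""Time-varying elastance chamber mechanics.

A cardiac chamber (atrium, whole ventricle, or a ventricular compartment
built from identical parallel units) is described by five constants:

* ``Emax`` -- slope of the end-systolic pressure-volume relation (ESPVR),
  in mmHg/ml;
* ``Tmax`` -- time from activation onset to peak elastance, in ms;
* ``A`` and ``B`` -- scale (mmHg) and exponent (1/ml) of the exponential
  end-diastolic pressure-volume relation (EDPVR),
  ``P_ed(V) = A * (exp(B * (V - V0)) - 1)``;
* ``V0`` -- unstressed volume (ml), the common zero-pressure intercept of
  both relations.

Instantaneous pressure interpolates between the two relations through an
activation function ``e(t)`` that rises from 0 at the activation onset to
1 at ``Tmax`` and returns to 0 over a relaxation window:

    P(V, t) = P_ed(V) + e(t) * (P_es(V) - P_ed(V))

The ventricle is assembled from 20 identical units in parallel; a
compartment holding a fraction ``f`` of the ventricle consists of
``n = 20 f`` units, whose parallel combination divides ``Emax`` and ``B``
by ``n`` and multiplies ``V0`` by ``n`` while leaving ``A`` and ``Tmax``
unchanged.  This scaling makes the two-compartment ventricle algebraically
identical to the single whole-ventricle chamber whenever the compartments
share a common pressure.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChamberParams",
    "ActivationSchedule",
    "N_VENTRICLE_UNITS",
    "activation_fraction",
    "end_diastolic_pressure",
    "end_systolic_pressure",
    "instantaneous_pressure",
    "compartment_parameters",
]

#: The ventricle is modelled as this many identical units in parallel;
#: one unit is the 5% building block of a compartment.
N_VENTRICLE_UNITS = 20


@dataclass(frozen=True)
class ChamberParams:
    """Elastance and EDPVR constants of one contractile chamber.

    Attributes
    ----------
    Emax : float
        Maximal (end-systolic) elastance, mmHg/ml.
    Tmax : float
        Time from activation onset to peak elastance, ms.
    A : float
        EDPVR scaling factor, mmHg.
    B : float
        EDPVR exponent, 1/ml.
    V0 : float
        Unstressed volume, ml.
    """

    Emax: float
    Tmax: float
    A: float
    B: float
    V0: float

    def __post_init__(self) -> None:
        for name in ("Emax", "Tmax", "A", "B", "V0"):
            value = getattr(self, name)
            if not (value > 0) or not math.isfinite(value):
                raise ValueError(f"ChamberParams.{name} must be positive, got {value!r}")


@dataclass(frozen=True)
class ActivationSchedule:
    """Onset times of the chambers within one cardiac cycle.

    All times in ms.  The atrium activates at ``atrial_onset``; both
    ventricular compartments activate at ``ventricular_onset`` (the atrial
    onset plus the PR interval), except that the delayed compartment is
    further postponed by ``delay_dT``.  Onsets are interpreted modulo the
    cycle length.
    """

    cycle_length: float
    atrial_onset: float = 0.0
    ventricular_onset: float = 100.0
    delay_dT: float = 0.0

    def __post_init__(self) -> None:
        if self.cycle_length <= 0:
            raise ValueError("cycle_length must be positive")
        if self.delay_dT < 0:
            raise ValueError("delay_dT must be non-negative")

    @property
    def delayed_onset(self) -> float:
        return self.ventricular_onset + self.delay_dT

    def phase(self, t: float, onset: float) -> float:
        """Time since ``onset`` within the current cycle."""
        return (t - onset) % self.cycle_length


def activation_fraction(t_since_onset, Tmax: float, relax_ratio: float = 0.5):
    """Activation ``e(t)`` of a chamber, dimensionless in [0, 1].

    A raised-cosine pulse: ``e`` rises over ``[0, Tmax)`` as
    ``(1 - cos(pi t/Tmax))/2``, relaxes over ``[Tmax, (1+relax_ratio) Tmax)``
    as ``(1 + cos(pi (t-Tmax)/(relax_ratio Tmax)))/2`` and is 0 thereafter.
    Continuous everywhere, with e(0) = 0 and e(Tmax) = 1.

    Parameters
    ----------
    t_since_onset : float or array
        Time since the chamber's activation onset, ms.  Must be >= 0.
    Tmax : float
        Time to peak elastance, ms.
    relax_ratio : float
        Duration of the relaxation branch as a fraction of ``Tmax``.
    """
    if Tmax <= 0:
        raise ValueError(f"Tmax must be positive, got {Tmax!r}")
    if relax_ratio <= 0:
        raise ValueError(f"relax_ratio must be positive, got {relax_ratio!r}")
    t = np.asarray(t_since_onset, dtype=float)
    if np.any(t < 0):
        raise ValueError("t_since_onset must be non-negative")
    rise = 0.5 * (1.0 - np.cos(np.pi * t / Tmax))
    fall = 0.5 * (1.0 + np.cos(np.pi * (t - Tmax) / (relax_ratio * Tmax)))
    e = np.where(t < Tmax, rise, np.where(t < (1.0 + relax_ratio) * Tmax, fall, 0.0))
    if np.ndim(t_since_onset) == 0:
        return float(e)
    return e


def end_diastolic_pressure(V, p: ChamberParams):
    """Passive (EDPVR) pressure ``A (exp(B (V - V0)) - 1)`` in mmHg.

    Zero at ``V = V0`` and strictly increasing in ``V``.  Volumes below
    ``V0`` yield negative pressure; this is deliberate, since a small
    compartment under paradoxical stretch by its neighbour can be pulled
    below its unstressed volume.
    """
    V = np.asarray(V, dtype=float)
    out = p.A * (np.exp(p.B * (V - p.V0)) - 1.0)
    return float(out) if out.ndim == 0 else out


def end_systolic_pressure(V, p: ChamberParams):
    """Active (ESPVR) pressure ``Emax (V - V0)`` in mmHg."""
    V = np.asarray(V, dtype=float)
    out = p.Emax * (V - p.V0)
    return float(out) if out.ndim == 0 else out


def instantaneous_pressure(V, t_since_onset, p: ChamberParams, relax_ratio: float = 0.5):
    """Chamber pressure at volume ``V`` and time ``t_since_onset`` (ms).

    ``P = P_ed(V) + e(t) (P_es(V) - P_ed(V))`` -- equals the passive EDPVR
    when the chamber is fully relaxed (e = 0) and the ESPVR line at peak
    activation (e = 1).
    """
    e = activation_fraction(t_since_onset, p.Tmax, relax_ratio)
    ped = end_diastolic_pressure(V, p)
    pes = end_systolic_pressure(V, p)
    return ped + e * (pes - ped)


def compartment_parameters(
    fraction: float, unit: ChamberParams, continuous: bool = False
) -> ChamberParams:
    """Parameters of a compartment made of ``n = 20 * fraction`` parallel units.

    Parameters
    ----------
    fraction : float
        Fraction of the total ventricle in (0, 1].  By default it must be a
        whole number of 5% units; pass ``continuous=True`` to allow any
        value (non-integer unit counts).
    unit : ChamberParams
        Parameters of one 5% unit.

    Returns
    -------
    ChamberParams
        ``Emax`` and ``B`` divided by ``n``, ``V0`` multiplied by ``n``,
        ``A`` and ``Tmax`` unchanged.
    """
    if not (0.0 < fraction <= 1.0):
        raise ValueError(f"fraction must be in (0, 1], got {fraction!r}")
    n = fraction * N_VENTRICLE_UNITS
    if not continuous and abs(n - round(n)) > 1e-6:
        raise ValueError(
            f"fraction {fraction!r} is not a whole number of 5% units; "
            "pass continuous=True to allow it"
        )
    if not continuous:
        n = round(n)
    return ChamberParams(
        Emax=unit.Emax / n,
        Tmax=unit.Tmax,
        A=unit.A,
        B=unit.B / n,
        V0=unit.V0 * n,
    )
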