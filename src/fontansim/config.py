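"""Circulation parameters and their YAML serialisation.

The default parameter set describes a typical postoperative Fontan
(total cavopulmonary connection) circulation of a 40-kg body: a single
ventricle assembled from 20 identical units, a single atrium, systemic
and pulmonary vascular beds connected in series, an inertial
atrioventricular valve and a resistive aortic valve.  Resistances are in
mmHg·s/ml, compliances in ml/mmHg, volumes in ml, times in ms at the
interface (seconds internally in the integrator).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chambers import ChamberParams, N_VENTRICLE_UNITS

__all__ = [
    "VascularBed",
    "AVValveParams",
    "CircuitParams",
    "default_params",
    "load_config",
    "save_config",
]


@dataclass(frozen=True)
class VascularBed:
    """Three-element Windkessel artery plus a compliant vein.

    ``Z_art`` is the characteristic impedance in series with the arterial
    compliance ``C_art``; ``R_art`` is the resistance draining it into the
    venous compliance ``C_ven``, which empties through ``R_ven``.
    """

    Z_art: float
    C_art: float
    R_art: float
    C_ven: float
    R_ven: float

    def __post_init__(self) -> None:
        for name in ("Z_art", "C_art", "R_art", "C_ven", "R_ven"):
            if getattr(self, name) <= 0:
                raise ValueError(f"VascularBed.{name} must be positive")


@dataclass(frozen=True)
class AVValveParams:
    """Atrioventricular valve: orifice Bernoulli loss plus blood inertance.

    The pressure loss of a flow Q (ml/s) through the orifice is
    ``rho * Q**2 / (2 * K * EOA**2)`` mmHg, with the effective orifice
    area ``EOA`` in cm^2, blood density ``rho`` in g/ml and the unit
    constant ``K`` in g s^-2 cm^-1 mmHg^-1.
    """

    EOA: float = 5.0
    L: float = 0.0003
    rho: float = 1.06
    K: float = 1333.0

    def __post_init__(self) -> None:
        for name in ("EOA", "L", "rho", "K"):
            if getattr(self, name) <= 0:
                raise ValueError(f"AVValveParams.{name} must be positive")


_GRID_FRACTIONS = tuple(round(0.05 * k, 2) for k in range(1, N_VENTRICLE_UNITS))


@dataclass(frozen=True)
class CircuitParams:
    """Full parameter set of the closed-loop Fontan circulation model."""

    atrium: ChamberParams
    ventricle_unit: ChamberParams
    systemic: VascularBed
    pulmonary: VascularBed
    av_valve: AVValveParams
    aortic_valve_R: float = 0.005
    intercompartment_R: float = 0.008
    HR: float = 80.0
    PR: float = 100.0
    total_stressed_volume: float = 720.0
    BSA: float = 1.35
    delayed_fraction: float = 0.5
    delay_dT: float = 0.0
    relax_ratio: float = 0.5
    #: which compartment receives atrioventricular inflow / feeds the aorta
    inflow_compartment: str = "earlier"
    outflow_compartment: str = "delayed"
    #: allow delayed_fraction off the 5% unit grid
    continuous_fraction: bool = False

    def __post_init__(self) -> None:
        for name in ("aortic_valve_R", "intercompartment_R", "HR", "PR",
                     "total_stressed_volume", "BSA"):
            if getattr(self, name) <= 0 and name != "PR":
                raise ValueError(f"CircuitParams.{name} must be positive")
        if self.delay_dT < 0:
            raise ValueError("delay_dT must be non-negative")
        if not (0.0 < self.delayed_fraction < 1.0):
            raise ValueError("delayed_fraction must be in (0, 1)")
        if not self.continuous_fraction:
            if not any(abs(self.delayed_fraction - g) < 1e-6 for g in _GRID_FRACTIONS):
                raise ValueError(
                    f"delayed_fraction {self.delayed_fraction!r} is not a multiple "
                    "of 0.05; set continuous_fraction=True to allow it"
                )
        if self.inflow_compartment not in ("earlier", "delayed"):
            raise ValueError("inflow_compartment must be 'earlier' or 'delayed'")
        if self.outflow_compartment not in ("earlier", "delayed"):
            raise ValueError("outflow_compartment must be 'earlier' or 'delayed'")

    @property
    def cycle_length_ms(self) -> float:
        return 60_000.0 / self.HR

    def replace(self, **changes) -> "CircuitParams":
        return dataclasses.replace(self, **changes)


def default_params(**overrides) -> CircuitParams:
    """Baseline Fontan parameter set (40-kg postoperative physiology)."""
    base = CircuitParams(
        atrium=ChamberParams(Emax=1.00, Tmax=120.0, A=0.80, B=0.08, V0=10.0),
        ventricle_unit=ChamberParams(Emax=62.0, Tmax=290.0, A=0.28, B=0.80, V0=0.77),
        systemic=VascularBed(Z_art=0.04, C_art=1.10, R_art=1.05, C_ven=35.0, R_ven=0.050),
        pulmonary=VascularBed(Z_art=0.01, C_art=2.5, R_art=0.040, C_ven=3.0, R_ven=0.010),
        av_valve=AVValveParams(EOA=5.0, L=0.0003, rho=1.06, K=1333.0),
    )
    return base.replace(**overrides) if overrides else base


def _chamber_to_dict(c: ChamberParams) -> dict:
    return {"E_max": c.Emax, "T_max": c.Tmax, "A": c.A, "B": c.B, "V_0": c.V0}


def _chamber_from_dict(d: dict) -> ChamberParams:
    return ChamberParams(Emax=d["E_max"], Tmax=d["T_max"], A=d["A"], B=d["B"], V0=d["V_0"])


def params_to_dict(p: CircuitParams) -> dict:
    return {
        "heart_rate": p.HR,
        "pr_interval_ms": p.PR,
        "total_stressed_volume_ml": p.total_stressed_volume,
        "body_surface_area_m2": p.BSA,
        "atrium": _chamber_to_dict(p.atrium),
        "ventricle_unit": _chamber_to_dict(p.ventricle_unit),
        "systemic": dataclasses.asdict(p.systemic),
        "pulmonary": dataclasses.asdict(p.pulmonary),
        "av_valve": dataclasses.asdict(p.av_valve),
        "aortic_valve": {"R": p.aortic_valve_R},
        "intercompartment": {"R": p.intercompartment_R},
        "delayed_fraction": p.delayed_fraction,
        "delay_dT_ms": p.delay_dT,
        "relax_ratio": p.relax_ratio,
        "inflow_compartment": p.inflow_compartment,
        "outflow_compartment": p.outflow_compartment,
    }


def params_from_dict(d: dict) -> CircuitParams:
    base = default_params()
    return CircuitParams(
        atrium=_chamber_from_dict(d["atrium"]) if "atrium" in d else base.atrium,
        ventricle_unit=(
            _chamber_from_dict(d["ventricle_unit"]) if "ventricle_unit" in d
            else base.ventricle_unit
        ),
        systemic=VascularBed(**d["systemic"]) if "systemic" in d else base.systemic,
        pulmonary=VascularBed(**d["pulmonary"]) if "pulmonary" in d else base.pulmonary,
        av_valve=AVValveParams(**d["av_valve"]) if "av_valve" in d else base.av_valve,
        aortic_valve_R=d.get("aortic_valve", {}).get("R", base.aortic_valve_R),
        intercompartment_R=d.get("intercompartment", {}).get("R", base.intercompartment_R),
        HR=d.get("heart_rate", base.HR),
        PR=d.get("pr_interval_ms", base.PR),
        total_stressed_volume=d.get("total_stressed_volume_ml", base.total_stressed_volume),
        BSA=d.get("body_surface_area_m2", base.BSA),
        delayed_fraction=d.get("delayed_fraction", base.delayed_fraction),
        delay_dT=d.get("delay_dT_ms", base.delay_dT),
        relax_ratio=d.get("relax_ratio", base.relax_ratio),
        inflow_compartment=d.get("inflow_compartment", base.inflow_compartment),
        outflow_compartment=d.get("outflow_compartment", base.outflow_compartment),
        continuous_fraction=d.get("continuous_fraction", False),
    )


def load_config(path: str | Path) -> CircuitParams:
    """Read a YAML parameter file; missing keys fall back to the defaults."""
    with open(path) as fh:
        return params_from_dict(yaml.safe_load(fh) or {})


def save_config(p: CircuitParams, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(params_to_dict(p), fh, sort_keys=False)
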