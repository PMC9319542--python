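"""Screening-level exposure: compartments, annual-average flux, soil PEC.

Near-field / far-field compartments
-----------------------------------
x50 defines the radius of a locally mixed near-field (NF) compartment
around the source; the regional far-field (FF) extends to xtot.  At
steady state, with deposition the only removal, the uniformly mixed
concentrations depend only on emission rate, compartment areas and the
deposition velocity:

    CN = E / (2*pi*x50**2 * vdep)
    CF = E / (2*pi*(xtot**2 - x50**2) * vdep)

Annual averaging and soil accumulation
--------------------------------------
A stability climatology P(a)...P(f) (frequencies of occurrence summing
to 1) weights per-class deposition-flux profiles into a yearly average
Favg = sum_i P(i)*F_i.  Continuous deposition for ``years`` years into
a uniform topsoil mixing layer gives

    PECsoil = Favg * years*365*24*3600 / (Hsoil * rho_soil)    [g/kg]

and the risk ratio PECsoil / PNECsoil flags potential effects when > 1.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

from .atmosphere import StabilityClass

__all__ = [
    "StabilityClimatology",
    "CompartmentResult",
    "SoilScenario",
    "nf_ff_concentrations",
    "weighted_average_flux",
    "pec_soil",
    "pec_pnec_ratio",
    "load_pnec_registry",
    "nf_to_ff_transfer_rate",
    "SECONDS_PER_YEAR",
]

SECONDS_PER_YEAR = 365 * 24 * 60 * 60  # 365-day year, by definition here

#: Northern-hemisphere average frequencies of occurrence of the stability
#: classes (combined day/night column).
DEFAULT_CLIMATOLOGY = {
    "a": 0.04,
    "b": 0.04,
    "c": 0.04,
    "d": 0.37,
    "e": 0.255,
    "f": 0.255,
}


@dataclass(frozen=True)
class StabilityClimatology:
    """Frequency of occurrence per stability class; must sum to 1."""

    P: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_CLIMATOLOGY))

    def __post_init__(self) -> None:
        p = {StabilityClass.coerce(k).value: float(v) for k, v in self.P.items()}
        missing = {c.value for c in StabilityClass} - set(p)
        if missing:
            raise ValueError(f"climatology missing classes: {sorted(missing)}")
        if any(v < 0 for v in p.values()):
            raise ValueError("climatology frequencies must be nonnegative")
        if abs(sum(p.values()) - 1.0) > 1e-6:
            raise ValueError("climatology frequencies must sum to 1")
        object.__setattr__(self, "P", p)

    def weight(self, stability: StabilityClass | str) -> float:
        return self.P[StabilityClass.coerce(stability).value]


@dataclass(frozen=True)
class CompartmentResult:
    """Uniformly mixed NF/FF concentrations (g/m3) and compartment sizes (m)."""

    CN: float
    CF: float
    x50: float
    xtot: float


def nf_ff_concentrations(E: float, vdep: float, x50: float, xtot: float) -> CompartmentResult:
    """Steady-state near-field and far-field concentrations.

    Raises for vdep <= 0 (no steady state without removal) and for
    x50 >= xtot (the far-field annulus vanishes).
    """
    if vdep <= 0:
        raise ValueError("vdep must be positive: steady state undefined without removal")
    if not 0 < x50 < xtot:
        raise ValueError("need 0 < x50 < xtot for distinct NF/FF compartments")
    cn = E / (2.0 * np.pi * x50**2 * vdep)
    cf = E / (2.0 * np.pi * (xtot**2 - x50**2) * vdep)
    return CompartmentResult(CN=float(cn), CF=float(cf), x50=x50, xtot=xtot)


def weighted_average_flux(
    per_class: Mapping[str, np.ndarray] | Mapping[StabilityClass, np.ndarray],
    clim: StabilityClimatology | None = None,
) -> np.ndarray:
    """Climatology-weighted average of per-class profiles on a common grid.

    Works for any per-class profile (deposition flux, concentration,
    deposited fraction): the average is a pointwise convex combination.
    """
    clim = clim or StabilityClimatology()
    profiles = {StabilityClass.coerce(k).value: np.asarray(v, float) for k, v in per_class.items()}
    missing = {c.value for c in StabilityClass} - set(profiles)
    if missing:
        raise ValueError(f"missing flux profile for classes: {sorted(missing)}")
    shapes = {p.shape for p in profiles.values()}
    if len(shapes) != 1:
        raise ValueError("per-class profiles must share a common grid")
    return sum(clim.P[c] * profiles[c] for c in profiles)


@dataclass(frozen=True)
class SoilScenario:
    """Topsoil accumulation parameters.

    Hsoil : uniform soil mixing depth (m).
    rho_soil : soil bulk density (kg/m3).
    years : accumulation time (yr).
    pnec_g_kg : predicted no-effect concentration in soil (g/kg).
    """

    Hsoil: float = 0.05
    rho_soil: float = 1500.0
    years: float = 100.0
    pnec_g_kg: float = 1e-3  # nano-TiO2 default: 1000 ug/kg

    def __post_init__(self) -> None:
        if min(self.Hsoil, self.rho_soil, self.years, self.pnec_g_kg) <= 0:
            raise ValueError("all soil-scenario parameters must be positive")


def pec_soil(favg, scenario: SoilScenario):
    """Predicted soil concentration (g/kg) after ``scenario.years`` of deposition.

    ``favg`` is the (average) deposition flux in g/m2/s, scalar or array.
    """
    favg = np.asarray(favg, dtype=float)
    return favg * scenario.years * SECONDS_PER_YEAR / (scenario.Hsoil * scenario.rho_soil)


def pec_pnec_ratio(favg, scenario: SoilScenario):
    """PECsoil / PNECsoil risk ratio (dimensionless; > 1 flags potential risk)."""
    return pec_soil(favg, scenario) / scenario.pnec_g_kg


def load_pnec_registry() -> dict[str, float]:
    """Packaged PNEC registry: substance -> PNEC in g/kg."""
    out: dict[str, float] = {}
    with resources.files("nanoplume.data").joinpath("pnec.csv").open() as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows):
            out[row["substance"]] = float(row["pnec_ug_kg"]) * 1e-6
    return out


def nf_to_ff_transfer_rate(*args, **kwargs):
    """Interface stub for the NF -> FF first-order transfer rate.

    The multicompartment transfer-rate formulation this would implement is
    not part of this package's validated scope; the steady-state
    :func:`nf_ff_concentrations` covers the screening use case.
    """
    raise NotImplementedError(
        "NF->FF transfer rate is an interface stub; use nf_ff_concentrations"
    )
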