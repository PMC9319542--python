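"""Particle settling and dry-deposition velocities.

Gravitational settling follows Stokes' law with the Cunningham slip
correction,

    vset = g * rho * Cc(dp, T) * dp**2 / (18 * eta(T)),

and the total dry-deposition velocity adds a resistance-limited surface
uptake term,

    vdep = vset + 1 / (ra + rc),

with ra the aerodynamic and rc the canopy (surface) resistance.  Three
interchangeable deposition models are provided:

* :class:`FixedDeposition` -- user-supplied vset/vdep (generic-pollutant
  mode, where the velocities are inputs rather than derived);
* :class:`CanopyDeposition` -- a semi-empirical resistance model for a
  forest canopy whose collection efficiency combines Brownian diffusion
  (Sc^-2/3) and interception (dp/L), calibrated against published
  nanoparticle eddy-covariance fluxes over a pine canopy: minimum
  deposition velocity near 100-150 nm, roughly 0.05-0.5 cm/s over
  10-500 nm, and a 10 nm particle depositing about an order of magnitude
  faster than a 100 nm one;
* :class:`TableDeposition` -- log-linear interpolation of a user lookup
  table (dp in nm -> vdep in m/s).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Protocol, runtime_checkable

import numpy as np

__all__ = [
    "ParticleSpec",
    "air_viscosity",
    "mean_free_path",
    "cunningham",
    "settling_velocity",
    "FixedDeposition",
    "CanopyDeposition",
    "TableDeposition",
    "VelocityModel",
    "Velocities",
]

G = 9.80665  # m/s^2
P_STD = 101_325.0  # Pa
BOLTZMANN = 1.380649e-23  # J/K

# Mean free path of air at the reference state below (m).
_LAMBDA_REF = 66.4e-9
_T_REF = 293.15
_SUTHERLAND = 110.4  # K


@dataclass(frozen=True)
class ParticleSpec:
    """A monodisperse particle: diameter ``dp`` in nm, density ``rho`` in kg/m3."""

    dp: float
    rho: float

    def __post_init__(self) -> None:
        if self.dp <= 0:
            raise ValueError("particle diameter dp must be positive")
        if self.rho <= 0:
            raise ValueError("particle density rho must be positive")

    @property
    def dp_m(self) -> float:
        return self.dp * 1e-9


def air_viscosity(T) -> np.ndarray:
    """Dynamic viscosity of air (Pa s) from Sutherland's law."""
    T = np.asarray(T, dtype=float)
    if np.any(T <= 0):
        raise ValueError("temperature must be positive (kelvin)")
    return 1.458e-6 * T**1.5 / (T + _SUTHERLAND)


def mean_free_path(T, pressure: float = P_STD) -> np.ndarray:
    """Mean free path of air molecules (m) at temperature T and pressure."""
    T = np.asarray(T, dtype=float)
    return (
        _LAMBDA_REF
        * (P_STD / pressure)
        * (T / _T_REF)
        * (1.0 + _SUTHERLAND / _T_REF)
        / (1.0 + _SUTHERLAND / T)
    )


def cunningham(dp_nm, T, pressure: float = P_STD) -> np.ndarray:
    """Cunningham slip correction factor (dimensionless, >= 1).

    Uses the Allen-Raabe form Cc = 1 + Kn*(1.257 + 0.4*exp(-1.1/Kn)) with
    Kn = 2*lambda/dp.  Monotone decreasing in dp, -> 1 for large particles.
    """
    dp = np.asarray(dp_nm, dtype=float) * 1e-9
    if np.any(dp <= 0):
        raise ValueError("particle diameter must be positive")
    kn = 2.0 * mean_free_path(T, pressure) / dp
    return 1.0 + kn * (1.257 + 0.4 * np.exp(-1.1 / kn))


def diffusivity(dp_nm, T, pressure: float = P_STD) -> np.ndarray:
    """Brownian diffusion coefficient of the particle in air (m2/s)."""
    dp = np.asarray(dp_nm, dtype=float) * 1e-9
    return BOLTZMANN * np.asarray(T, float) * cunningham(dp_nm, T, pressure) / (
        3.0 * np.pi * air_viscosity(T) * dp
    )


def settling_velocity(p: ParticleSpec, T: float, pressure: float = P_STD) -> float:
    """Stokes settling velocity with slip correction (m/s)."""
    cc = cunningham(p.dp, T, pressure)
    return float(G * p.rho * cc * p.dp_m**2 / (18.0 * air_viscosity(T)))


@dataclass(frozen=True)
class Velocities:
    """Settling and total dry-deposition velocity pair (m/s)."""

    vset: float
    vdep: float

    def __post_init__(self) -> None:
        if self.vset < 0 or self.vdep < 0:
            raise ValueError("velocities must be nonnegative")


@runtime_checkable
class VelocityModel(Protocol):
    """Anything that can produce (vset, vdep) for given particle/temperature."""

    def velocities(self, particle: ParticleSpec | None, T: float) -> Velocities: ...


@dataclass(frozen=True)
class FixedDeposition:
    """Fixed, user-supplied velocities; the generic-pollutant mode.

    vset and vdep are independent inputs here (no vdep >= vset constraint
    is imposed: the pair comes straight from the scenario table).
    """

    vset: float
    vdep: float

    def velocities(self, particle: ParticleSpec | None = None, T: float = 288.15) -> Velocities:
        return Velocities(self.vset, self.vdep)


@dataclass(frozen=True)
class CanopyDeposition:
    """Resistance-model deposition over a forest canopy.

    vdep = vset + 1/(ra + rc) with rc = 1/(ustar * (Sc^-2/3 + dp/collector_scale)).

    Parameters (defaults documented in docs/methods.md):

    ustar : friction velocity (m/s); scales the surface conductance.
    ra : aerodynamic resistance (s/m) above the canopy.
    collector_scale : effective interception length (m).  An aggregate of
        needle/leaf fine structure; small values strengthen interception
        of >100 nm particles.
    pressure : ambient pressure (Pa).
    """

    ustar: float = 0.3
    ra: float = 50.0
    collector_scale: float = 1e-4
    pressure: float = P_STD

    def __post_init__(self) -> None:
        if self.ustar <= 0 or self.collector_scale <= 0:
            raise ValueError("ustar and collector_scale must be positive")
        if self.ra < 0:
            raise ValueError("aerodynamic resistance must be nonnegative")

    def canopy_resistance(self, particle: ParticleSpec, T: float) -> float:
        nu = air_viscosity(T) / self._air_density(T)
        sc = nu / diffusivity(particle.dp, T, self.pressure)
        efficiency = sc ** (-2.0 / 3.0) + particle.dp_m / self.collector_scale
        return float(1.0 / (self.ustar * efficiency))

    def _air_density(self, T: float) -> float:
        return self.pressure / (287.05 * T)

    def velocities(self, particle: ParticleSpec | None, T: float) -> Velocities:
        if particle is None:
            raise ValueError("CanopyDeposition requires a ParticleSpec")
        vset = settling_velocity(particle, T, self.pressure)
        rc = self.canopy_resistance(particle, T)
        if self.ra + rc <= 0:
            raise ValueError("total resistance ra + rc must be positive")
        return Velocities(vset, vset + 1.0 / (self.ra + rc))


@dataclass(frozen=True)
class TableDeposition:
    """Deposition velocity from a two-column lookup table, log-linear in dp.

    ``dp_nm`` and ``vdep_m_s`` are parallel sequences; vset is computed
    from the particle spec when available (zero otherwise).
    """

    dp_nm: tuple[float, ...]
    vdep_m_s: tuple[float, ...]

    def __post_init__(self) -> None:
        dp = np.asarray(self.dp_nm, float)
        vd = np.asarray(self.vdep_m_s, float)
        if dp.size != vd.size or dp.size < 2:
            raise ValueError("lookup table needs >= 2 matching (dp, vdep) rows")
        if np.any(dp <= 0) or np.any(vd <= 0) or np.any(np.diff(dp) <= 0):
            raise ValueError("table must have increasing dp > 0 and vdep > 0")

    @classmethod
    def from_csv(cls, path) -> "TableDeposition":
        data = np.loadtxt(path, delimiter=",", comments="#", skiprows=1, ndmin=2)
        return cls(tuple(data[:, 0]), tuple(data[:, 1]))

    def velocities(self, particle: ParticleSpec | None, T: float) -> Velocities:
        if particle is None:
            raise ValueError("TableDeposition requires a ParticleSpec (for dp)")
        logv = np.interp(
            np.log(particle.dp), np.log(self.dp_nm), np.log(self.vdep_m_s)
        )
        vset = settling_velocity(particle, T)
        return Velocities(vset, float(np.exp(logv)))
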