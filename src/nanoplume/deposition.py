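"""Ground deposition fluxes, deposited/suspended fractions, and x50.

The ground flux magnitude is F(x, y) = vdep * C(x, y, 2 m) (the sign in
the governing equation only encodes direction).  Integrating the flux
crosswind (analytic: the Gaussian y-profile integrates to
sqrt(2*pi)*sigma_y times the centerline value) and then downwind gives
the net deposition rate Rdep(x) (g/s) and the deposited fraction
fdep(x) = Rdep(x)/E.  The suspended fraction fsusp(x) is the horizontal
mass flux through the vertical plane at x divided by E.  After the
mass-balance correction fdep + fsusp = 1 on every grid point.

x50 -- the downwind distance at which half the emitted mass has
deposited, fdep(x50) = 0.5 -- separates the local (near-field) from the
regional (far-field) exposure scale.  When fdep never reaches 0.5
inside the domain the profile reports ``math.inf`` ("beyond domain").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .plume import SQRT2PI, PlumeSolution

__all__ = [
    "DepositionProfile",
    "deposition_flux",
    "net_deposition_rate",
    "deposited_fraction",
    "suspended_fraction",
    "x50_distance",
    "BEYOND_DOMAIN",
]

BEYOND_DOMAIN = math.inf
"""Sentinel x50 value: less than half the mass deposits inside the domain."""


@dataclass
class DepositionProfile:
    """Per-distance deposition bookkeeping for one solved plume.

    Attributes
    ----------
    x : downwind grid (m).
    flux : centerline ground flux magnitude vdep*C(x, 0, 2) (g/m2/s).
    cwi_flux : crosswind-integrated flux (g/m/s).
    Rdep : cumulative net deposition rate between the source and x (g/s).
    fdep, fsusp : deposited and suspended fractions of the emission.
    x50 : half-deposited distance (m) or ``math.inf`` when beyond the domain.
    xtot : domain radius (m).
    """

    x: np.ndarray
    flux: np.ndarray
    cwi_flux: np.ndarray
    Rdep: np.ndarray
    fdep: np.ndarray
    fsusp: np.ndarray
    x50: float
    xtot: float
    E: float
    vdep: float

    @classmethod
    def from_solution(cls, sol: PlumeSolution) -> "DepositionProfile":
        vdep = sol.vel.vdep
        flux = vdep * sol.conc_ground
        cwi = SQRT2PI * sol.sigma_y * flux
        rdep = sol.fdep * sol.source.E
        return cls(
            x=sol.x,
            flux=flux,
            cwi_flux=cwi,
            Rdep=rdep,
            fdep=sol.fdep,
            fsusp=sol.fsusp,
            x50=x50_from_arrays(sol.x, sol.fdep),
            xtot=float(sol.x[-1]),
            E=sol.source.E,
            vdep=vdep,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x_m": self.x,
                "flux_g_m2_s": self.flux,
                "cwi_flux_g_m_s": self.cwi_flux,
                "Rdep_g_s": self.Rdep,
                "fdep": self.fdep,
                "fsusp": self.fsusp,
            }
        )

    def _interp(self, values: np.ndarray, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x < self.x[0]) or np.any(x > self.x[-1]):
            raise ValueError(
                f"x outside deposition grid [{self.x[0]:.3g}, {self.x[-1]:.3g}] m"
            )
        return np.interp(np.log(x), np.log(self.x), values)


def deposition_flux(sol: PlumeSolution, x, y=0.0):
    """Ground deposition flux magnitude vdep*C(x, y, 2 m), g/m2/s."""
    return sol.vel.vdep * sol.concentration(x, y, sol.z_ref)


def net_deposition_rate(profile: DepositionProfile, x):
    """Cumulative deposition rate Rdep(x) in g/s (log-linear between grid points)."""
    return profile._interp(profile.Rdep, x)


def deposited_fraction(profile: DepositionProfile, x):
    """fdep(x) = Rdep(x)/E, dimensionless."""
    return profile._interp(profile.fdep, x)


def suspended_fraction(profile: DepositionProfile, x):
    """fsusp(x): fraction of the emission still airborne at the plane x."""
    return profile._interp(profile.fsusp, x)


def x50_from_arrays(x: np.ndarray, fdep: np.ndarray) -> float:
    """Half-deposited distance by log-linear interpolation of fdep over x."""
    fdep = np.asarray(fdep, dtype=float)
    if np.any(np.diff(fdep) < -1e-9):
        raise ValueError("fdep must be nondecreasing to define x50")
    if fdep[-1] < 0.5:
        return BEYOND_DOMAIN
    i = int(np.searchsorted(fdep, 0.5))
    if fdep[i] == 0.5 or i == 0:
        return float(x[i])
    # log-linear in x between the bracketing grid points
    f0, f1 = fdep[i - 1], fdep[i]
    lx = np.log(x[i - 1]) + (0.5 - f0) / (f1 - f0) * (np.log(x[i]) - np.log(x[i - 1]))
    return float(np.exp(lx))


def x50_distance(profile: DepositionProfile) -> float:
    """x50 of a profile; ``math.inf`` when fdep(xtot) < 0.5."""
    return profile.x50
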