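"""Point-source plume concentration fields for depositing aerosols.

Four nested formulations of the steady-state concentration C(x, y, z)
(g/m3) downwind of a continuous point source of strength E (g/s) at
height H:

``classic``
    Gaussian plume with ground reflection, valid for a non-depositing
    gas in an unbounded atmosphere.
``ermak``
    Ermak's analytical solution for a plume losing mass to the ground
    at deposition velocity vdep while settling at vset (in Rao's
    simplified form).  Collapses exactly to ``classic`` when
    vdep = vset = 0.
``rao``
    Ermak's solution extended with boundary-layer reflections: image
    sources at effective heights |H + 2*j*hpbl| summed over
    j = -j_max ... j_max (absolute value so that ground images deposit
    and lid images do not, rather than the reverse).  With
    vdep = vset = 0 this is the Yamartino reflecting-lid plume.
``rao_mass_balanced``
    The ``rao`` field rescaled per downwind distance so that the
    deposited plus suspended fractions of the emitted mass sum to one;
    the recommended default (the uncorrected series over-predicts near
    the source).

Numerics: the erfc*exp(xi^2) factor is evaluated with
``scipy.special.erfcx`` and all Gaussian exponents are combined before
exponentiation, so the field is finite for arbitrarily small sigma_z.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import erfcx

from .atmosphere import AtmosphericState
from .particle import Velocities

__all__ = [
    "SourceSpec",
    "ConcentrationQuery",
    "PlumeModel",
    "PlumeSolution",
    "concentration_classic",
    "concentration_ermak",
    "concentration_rao",
    "mass_balance_correct",
    "max_ground_concentration",
    "default_grid",
]

SQRT2PI = float(np.sqrt(2.0 * np.pi))
GROUND_LEVEL = 2.0  # m; conventional ground-level evaluation height
DEFAULT_JMAX = 10
DEFAULT_X_MIN = 10.0  # m, smallest supported evaluation distance
DEFAULT_X_MAX = 500_000.0  # m, default domain radius
POINTS_PER_DECADE = 50


class MassBalanceError(RuntimeError):
    """Raised when the per-distance mass-balance iteration fails to converge."""


@dataclass(frozen=True)
class SourceSpec:
    """Continuous point source: emission rate E (g/s) at stack height H (m)."""

    E: float
    H: float

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValueError("emission rate E must be positive")
        if self.H < 0:
            raise ValueError("source height H must be nonnegative")


@dataclass(frozen=True)
class ConcentrationQuery:
    """A single evaluation point (x downwind, y crosswind, z height), metres."""

    x: float
    y: float = 0.0
    z: float = GROUND_LEVEL

    def __post_init__(self) -> None:
        if self.x <= 0:
            raise ValueError("downwind distance x must be positive")
        if self.z < 0:
            raise ValueError("height z must be nonnegative")


def default_grid(
    x_min: float = DEFAULT_X_MIN,
    x_max: float = DEFAULT_X_MAX,
    points_per_decade: int = POINTS_PER_DECADE,
) -> np.ndarray:
    """Geometric downwind grid, ``points_per_decade`` points per decade."""
    if not 0 < x_min < x_max:
        raise ValueError("need 0 < x_min < x_max")
    n = int(round(np.log10(x_max / x_min) * points_per_decade)) + 1
    return np.geomspace(x_min, x_max, max(n, 2))


# ---------------------------------------------------------------------------
# Elementary vertical terms


def _check_xyz(x, z):
    x = np.asarray(x, dtype=float)
    z = np.asarray(z, dtype=float)
    if np.any(x <= 0):
        raise ValueError("downwind distance x must be positive")
    if np.any(z < 0):
        raise ValueError("height z must be nonnegative")
    return x, z


def _vertical_term(z, h, sigz, kz, vset, v0):
    """One depositing image term of the vertical profile (dimensionless).

    exp-arguments are combined analytically: with t = vset*sigz/(2*Kz) the
    settling prefactor times the direct Gaussian is exp(-((z-h)/sigz+t)^2/2),
    which is bounded for all inputs.
    """
    t = vset * sigz / (2.0 * kz)
    zm = (z - h) / sigz
    zp = (z + h) / sigz
    direct = np.exp(-0.5 * (zm + t) ** 2)
    reflected = np.exp(-(zm * t) - 0.5 * t * t - 0.5 * zp * zp)
    xi = (zp + v0 * sigz / kz) / np.sqrt(2.0)
    depletion = 1.0 - SQRT2PI * (v0 * sigz / kz) * erfcx(xi)
    return direct + reflected * depletion


def _gaussian_y(y, sigy):
    return np.exp(-0.5 * (np.asarray(y, float) / sigy) ** 2)


def _prefactor(src: SourceSpec, atm: AtmosphericState, sigy, sigz):
    return src.E / (2.0 * np.pi * atm.U * sigy * sigz)


def _clamp(c):
    """Clamp tiny negative values from floating cancellation in the image sum."""
    c = np.asarray(c)
    if np.any(c < -1e-9 * np.max(np.abs(c), initial=0.0)):
        warnings.warn("negative concentration from image-sum cancellation clamped to 0")
    return np.maximum(c, 0.0)


# ---------------------------------------------------------------------------
# Public concentration formulations (broadcast over x, y, z)


def concentration_classic(x, y, z, src: SourceSpec, atm: AtmosphericState):
    """Classic Gaussian plume with ground reflection (g/m3)."""
    x, z = _check_xyz(x, z)
    sigy, sigz = atm.sigma_y(x), atm.sigma_z(x)
    zm, zp = (z - src.H) / sigz, (z + src.H) / sigz
    vert = np.exp(-0.5 * zm * zm) + np.exp(-0.5 * zp * zp)
    return _prefactor(src, atm, sigy, sigz) * _gaussian_y(y, sigy) * vert


def concentration_ermak(x, y, z, src: SourceSpec, atm: AtmosphericState, vel: Velocities):
    """Depositing plume without boundary-layer reflection (g/m3)."""
    x, z = _check_xyz(x, z)
    sigy, sigz = atm.sigma_y(x), atm.sigma_z(x)
    kz = atm.U * sigz**2 / (2.0 * x)
    v0 = vel.vdep - 0.5 * vel.vset
    vert = _vertical_term(z, src.H, sigz, kz, vel.vset, v0)
    return _clamp(_prefactor(src, atm, sigy, sigz) * _gaussian_y(y, sigy) * vert)


def _rao_vertical(z, src: SourceSpec, atm: AtmosphericState, vel: Velocities, sigz, kz, j_max):
    v0 = vel.vdep - 0.5 * vel.vset
    total = 0.0
    for j in range(-j_max, j_max + 1):
        h = abs(src.H + 2.0 * j * atm.hpbl)
        total = total + _vertical_term(z, h, sigz, kz, vel.vset, v0)
    return total


def concentration_rao(
    x, y, z, src: SourceSpec, atm: AtmosphericState, vel: Velocities, j_max: int = DEFAULT_JMAX
):
    """Depositing plume with boundary-layer image reflections (g/m3)."""
    if j_max < 1:
        raise ValueError("j_max must be >= 1")
    if atm.hpbl <= 0:
        raise ValueError("boundary-layer height must be positive")
    x, z = _check_xyz(x, z)
    sigy, sigz = atm.sigma_y(x), atm.sigma_z(x)
    kz = atm.U * sigz**2 / (2.0 * x)
    vert = _rao_vertical(z, src, atm, vel, sigz, kz, j_max)
    return _clamp(_prefactor(src, atm, sigy, sigz) * _gaussian_y(y, sigy) * vert)


# ---------------------------------------------------------------------------
# Mass-balance corrected solution on a grid


def _z_quadrature_nodes(x, sigz, H, hpbl, n_base=81, n_plume=49, n_edge=25):
    """Per-distance vertical nodes resolving both the layer and the thin plume."""
    nx = x.size
    base = np.broadcast_to(np.linspace(0.0, hpbl, n_base), (nx, n_base))
    off = np.linspace(-8.0, 8.0, n_plume)
    pos = np.linspace(0.0, 8.0, n_edge)
    s = sigz[:, None]
    nodes = np.concatenate(
        [base, H + s * off, s * pos, hpbl - s * pos], axis=1
    )
    np.clip(nodes, 0.0, hpbl, out=nodes)
    nodes.sort(axis=1)
    return nodes


@dataclass
class PlumeSolution:
    """A (possibly mass-balance-corrected) plume on a downwind grid.

    ``correction`` is the per-distance scalar multiplying the raw ``rao``
    field; all stored profiles are already corrected.  ``conc_ground`` is
    the centerline concentration at ``z_ref`` (g/m3).
    """

    source: SourceSpec
    atm: AtmosphericState
    vel: Velocities
    x: np.ndarray
    correction: np.ndarray
    conc_ground: np.ndarray
    sigma_y: np.ndarray
    sigma_z: np.ndarray
    fdep: np.ndarray
    fsusp: np.ndarray
    model: str = "rao_mass_balanced"
    j_max: int = DEFAULT_JMAX
    z_ref: float = GROUND_LEVEL

    def concentration(self, x, y=0.0, z=GROUND_LEVEL):
        """Corrected concentration at arbitrary points inside the grid span."""
        x = np.asarray(x, dtype=float)
        raw = concentration_rao(x, y, z, self.source, self.atm, self.vel, self.j_max)
        phi = np.interp(np.log(x), np.log(self.x), self.correction)
        return raw * phi

    def max_ground(self) -> tuple[float, float]:
        """(Cmax, x_at_max): grid maximum of the centerline ground concentration."""
        i = int(np.argmax(self.conc_ground))
        return float(self.conc_ground[i]), float(self.x[i])


class PlumeModel:
    """Solver wrapping one source/atmosphere/velocity configuration.

    Parameters
    ----------
    model : one of ``classic``, ``ermak``, ``rao``, ``rao_mass_balanced``.
    j_max : reflection truncation order for the image sum.
    z_ref : ground-level evaluation height (m), 2 m by convention.
    """

    def __init__(
        self,
        source: SourceSpec,
        atm: AtmosphericState,
        vel: Velocities = Velocities(0.0, 0.0),
        model: str = "rao_mass_balanced",
        j_max: int = DEFAULT_JMAX,
        z_ref: float = GROUND_LEVEL,
    ):
        if model not in ("classic", "ermak", "rao", "rao_mass_balanced"):
            raise ValueError(f"unknown plume model {model!r}")
        self.source, self.atm, self.vel = source, atm, vel
        self.model, self.j_max, self.z_ref = model, j_max, z_ref

    # raw (uncorrected) field -------------------------------------------------
    def concentration_raw(self, x, y=0.0, z=None):
        z = self.z_ref if z is None else z
        if self.model == "classic":
            return concentration_classic(x, y, z, self.source, self.atm)
        if self.model == "ermak":
            return concentration_ermak(x, y, z, self.source, self.atm, self.vel)
        return concentration_rao(x, y, z, self.source, self.atm, self.vel, self.j_max)

    def _suspended_fraction_raw(self, x: np.ndarray, sigz: np.ndarray) -> np.ndarray:
        """fsusp of the uncorrected field: int_0^hpbl U*C_cwi dz / E.

        The crosswind integral of the Gaussian y-profile is sqrt(2*pi)*sigma_y
        times the centerline value, so sigma_y cancels and the integrand is the
        vertical term divided by sqrt(2*pi)*sigma_z.  The upper limit is the
        boundary-layer top: the image sources fold all suspended mass into
        [0, hpbl].
        """
        kz = self.atm.U * sigz**2 / (2.0 * x)
        znodes = _z_quadrature_nodes(x, sigz, self.source.H, self.atm.hpbl)
        vert = _rao_vertical(
            znodes, self.source, self.atm, self.vel, sigz[:, None], kz[:, None], self.j_max
        )
        vert = np.maximum(vert, 0.0)
        integral = np.trapezoid(vert, znodes, axis=1)
        return integral / (SQRT2PI * sigz)

    def solve(
        self,
        x_grid: np.ndarray | None = None,
        tol: float = 0.01,
        max_iter: int = 100,
    ) -> PlumeSolution:
        """Evaluate the plume on a grid; apply the mass-balance correction
        when the model is ``rao_mass_balanced``.

        The correction iterates C <- C / (fdep + fsusp) per grid distance,
        marching downwind so the cumulative deposition integral uses already
        corrected upstream flux, until |1 - fdep - fsusp| < ``tol``
        everywhere.  Within one sweep the fixed point is solved exactly
        (the residual is linear in the local factor), so convergence takes
        one to two sweeps.
        """
        x = default_grid() if x_grid is None else np.asarray(x_grid, dtype=float)
        if x.ndim != 1 or x.size < 2 or np.any(np.diff(x) <= 0):
            raise ValueError("x_grid must be a monotone increasing 1-D array")
        sigy, sigz = self.atm.sigma_y(x), self.atm.sigma_z(x)

        ground_raw = self.concentration_raw(x, 0.0, self.z_ref)

        if self.model != "rao_mass_balanced":
            # No correction: report bookkeeping fractions of the raw field.
            phi = np.ones_like(x)
            fdep, fsusp = self._fractions(x, ground_raw, sigy, sigz, phi)
            return self._package(x, phi, ground_raw, sigy, sigz, fdep, fsusp)

        s = self._suspended_fraction_raw(x, sigz)
        # Per-metre fractional deposition rate of the raw field: the crosswind
        # integrated ground flux vdep*sqrt(2pi)*sigy*C(x,0,zref) divided by E.
        w = self.vel.vdep * SQRT2PI * sigy * ground_raw / self.source.E

        phi = np.ones_like(x)
        for _ in range(max_iter):
            phi_new = np.empty_like(phi)
            fdep = np.empty_like(phi)
            phi_new[0] = 1.0 / s[0] if s[0] > 0 else 1.0
            fdep[0] = 0.0
            cum = 0.0
            for i in range(1, x.size):
                dx = x[i] - x[i - 1]
                a = 0.5 * dx * w[i - 1] * phi_new[i - 1]
                b = 0.5 * dx * w[i]
                denom = s[i] + b
                phi_new[i] = max((1.0 - cum - a) / denom, 0.0) if denom > 0 else 1.0
                cum += a + b * phi_new[i]
                fdep[i] = cum
            fsusp = phi_new * s
            phi = phi_new
            resid = np.abs(1.0 - fdep - fsusp)
            if np.max(resid) < tol:
                break
        else:
            i = int(np.argmax(resid))
            raise MassBalanceError(
                f"mass balance not converged: worst residual {resid[i]:.3g} at x={x[i]:.3g} m"
            )
        return self._package(x, phi, ground_raw * phi, sigy, sigz, fdep, fsusp)

    def _fractions(self, x, ground, sigy, sigz, phi):
        w = self.vel.vdep * SQRT2PI * sigy * ground / self.source.E
        fdep = np.concatenate([[0.0], np.cumsum(0.5 * np.diff(x) * (w[1:] + w[:-1]))])
        fsusp = self._suspended_fraction_raw(x, sigz) * phi if self.model.startswith("rao") else (
            1.0 - fdep
        )
        return fdep, fsusp

    def _package(self, x, phi, ground, sigy, sigz, fdep, fsusp) -> PlumeSolution:
        return PlumeSolution(
            source=self.source,
            atm=self.atm,
            vel=self.vel,
            x=x,
            correction=phi,
            conc_ground=ground,
            sigma_y=sigy,
            sigma_z=sigz,
            fdep=fdep,
            fsusp=fsusp,
            model=self.model,
            j_max=self.j_max,
            z_ref=self.z_ref,
        )


def mass_balance_correct(
    source: SourceSpec,
    atm: AtmosphericState,
    vel: Velocities,
    x_grid: np.ndarray | None = None,
    j_max: int = DEFAULT_JMAX,
    tol: float = 0.01,
    max_iter: int = 100,
) -> PlumeSolution:
    """Solve the reflected depositing plume and enforce fdep + fsusp = 1."""
    return PlumeModel(source, atm, vel, "rao_mass_balanced", j_max).solve(
        x_grid, tol=tol, max_iter=max_iter
    )


def max_ground_concentration(
    source: SourceSpec,
    atm: AtmosphericState,
    vel: Velocities,
    x_grid: np.ndarray | None = None,
) -> tuple[float, float]:
    """(Cmax g/m3, x_at_max m) of the corrected centerline ground concentration."""
    return mass_balance_correct(source, atm, vel, x_grid).max_ground()
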