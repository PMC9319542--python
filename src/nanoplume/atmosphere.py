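"""Atmospheric state and Pasquill-stability dispersion parameters.

The plume width grows with downwind distance according to empirical
dispersion parameters sigma_y(x) and sigma_z(x).  Two parametrizations
keyed on the Pasquill stability classes a (extremely unstable) ... f
(stable) are shipped:

* ``klug`` -- pure power laws ``sigma = R * x**r`` with x in metres
  (Klug 1969, as tabulated by Seinfeld & Pandis, Table 18.3);
* ``davidson`` -- modified power laws ``sigma = a * x**(b + c*ln(x))``
  with x in kilometres (Davidson 1990), a smooth fit of the
  Pasquill-Gifford/Briggs curves.

All public interfaces take x in metres; the Davidson km conversion is
internal.  Vertical dispersion is capped at 5000 m, the conventional
mixing limit used with these curves (unstable classes otherwise grow
without physical bound).
"""

from __future__ import annotations

import csv
import enum
from dataclasses import dataclass, field
from importlib import resources
from typing import Mapping

import numpy as np

__all__ = [
    "StabilityClass",
    "DispersionScheme",
    "AtmosphericState",
    "sigma_y",
    "sigma_z",
]

SIGMA_Z_CAP = 5000.0
"""Default vertical-dispersion cap in metres."""


class StabilityClass(str, enum.Enum):
    """Pasquill stability class, a (extremely unstable) to f (stable)."""

    A = "a"
    B = "b"
    C = "c"
    D = "d"
    E = "e"
    F = "f"

    @classmethod
    def coerce(cls, value: "StabilityClass | str") -> "StabilityClass":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _read_coefficients(name: str) -> dict[str, dict[str, float]]:
    table: dict[str, dict[str, float]] = {}
    with resources.files("nanoplume.data").joinpath(f"{name}.csv").open() as fh:
        rows = (line for line in fh if not line.startswith("#"))
        for row in csv.DictReader(rows):
            table.setdefault(row["class"], {})[row["coefficient"]] = float(row["value"])
    return table


@dataclass(frozen=True)
class DispersionScheme:
    """A named sigma_y/sigma_z parametrization with per-class coefficients.

    ``coefficients`` maps stability-class label -> coefficient name -> value.
    Klug rows carry (Ry, ry, Rz, rz); Davidson rows (ay, by, cy, az, bz, cz).
    """

    name: str
    coefficients: Mapping[str, Mapping[str, float]]
    sigma_z_cap: float = SIGMA_Z_CAP

    def __post_init__(self) -> None:
        if self.sigma_z_cap <= 0:
            raise ValueError("sigma_z_cap must be positive")
        missing = {c.value for c in StabilityClass} - set(self.coefficients)
        if missing:
            raise ValueError(f"scheme {self.name!r} lacks classes: {sorted(missing)}")

    @classmethod
    def from_name(cls, name: str, sigma_z_cap: float = SIGMA_Z_CAP) -> "DispersionScheme":
        name = name.lower()
        if name not in ("klug", "davidson"):
            raise ValueError(f"unknown dispersion scheme {name!r}")
        return cls(name=name, coefficients=_read_coefficients(name), sigma_z_cap=sigma_z_cap)

    # -- evaluation ---------------------------------------------------------

    def _check_x(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        if np.any(x <= 0.0):
            raise ValueError("downwind distance x must be positive")
        return x

    def sigma_y(self, x, stability: StabilityClass | str):
        """Crosswind dispersion width (m) at downwind distance x (m)."""
        x = self._check_x(x)
        c = self.coefficients[StabilityClass.coerce(stability).value]
        if self.name == "klug":
            return c["Ry"] * x ** c["ry"]
        xk = x / 1000.0
        return c["ay"] * xk ** (c["by"] + c["cy"] * np.log(xk))

    def sigma_z(self, x, stability: StabilityClass | str):
        """Vertical dispersion width (m), capped at ``sigma_z_cap``."""
        x = self._check_x(x)
        c = self.coefficients[StabilityClass.coerce(stability).value]
        if self.name == "klug":
            raw = c["Rz"] * x ** c["rz"]
        else:
            xk = x / 1000.0
            # Exponent is quadratic in ln(x); clip to avoid overflow before the cap.
            expo = np.clip((c["bz"] + c["cz"] * np.log(xk)) * np.log(xk), None, 500.0)
            raw = c["az"] * np.exp(expo)
        return np.minimum(raw, self.sigma_z_cap)


_SCHEME_CACHE: dict[tuple[str, float], DispersionScheme] = {}


def get_scheme(name: "str | DispersionScheme", sigma_z_cap: float = SIGMA_Z_CAP) -> DispersionScheme:
    if isinstance(name, DispersionScheme):
        return name
    key = (name.lower(), sigma_z_cap)
    if key not in _SCHEME_CACHE:
        _SCHEME_CACHE[key] = DispersionScheme.from_name(name, sigma_z_cap)
    return _SCHEME_CACHE[key]


@dataclass(frozen=True)
class AtmosphericState:
    """Steady meteorology driving a single plume calculation.

    Parameters
    ----------
    U : wind speed (m/s), constant along the plume axis.
    T : air temperature (K); used for air viscosity and slip correction.
    hpbl : planetary boundary-layer height (m), the reflecting lid.
    stability : Pasquill class label a-f.
    scheme : dispersion parametrization, ``"klug"`` or ``"davidson"``
        (or a ready :class:`DispersionScheme`).
    """

    U: float
    T: float
    hpbl: float
    stability: StabilityClass = StabilityClass.D
    scheme: DispersionScheme = field(default_factory=lambda: get_scheme("davidson"))

    def __post_init__(self) -> None:
        if self.U <= 0:
            raise ValueError("wind speed U must be positive")
        if self.T <= 0:
            raise ValueError("temperature T must be positive (kelvin)")
        if self.hpbl <= 0:
            raise ValueError("boundary-layer height hpbl must be positive")
        object.__setattr__(self, "stability", StabilityClass.coerce(self.stability))
        if isinstance(self.scheme, str):
            object.__setattr__(self, "scheme", get_scheme(self.scheme))

    def replace(self, **kw) -> "AtmosphericState":
        from dataclasses import replace

        return replace(self, **kw)

    def sigma_y(self, x):
        return self.scheme.sigma_y(x, self.stability)

    def sigma_z(self, x):
        return self.scheme.sigma_z(x, self.stability)


def sigma_y(x, state: AtmosphericState):
    """Crosswind plume width sigma_y(x) in metres for the given state."""
    return state.sigma_y(x)


def sigma_z(x, state: AtmosphericState):
    """Vertical plume width sigma_z(x) in metres (capped) for the given state."""
    return state.sigma_z(x)
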