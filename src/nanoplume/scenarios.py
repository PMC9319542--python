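"""Scenario configuration, case studies, parameter sweeps and run reports.

A :class:`Scenario` bundles everything one plume calculation needs:
source, particle (or fixed velocities), meteorology, domain and an
optional soil/climatology block.  Configurations are human-editable
YAML with explicit unit strings ("29 ug/s", "7.8 m", "1 km"); all
values are converted to SI at the parse boundary and serialized back in
the same display units, so parse -> serialize is idempotent.

Two TiO2 release case studies are built in:

* ``fonseca``  -- paint-factory stack (H = 7.8 m, dp = 260 nm,
  rho = 940 kg/m3), yearly-average emission 29 ug/s, powder-pouring
  activity emission 0.14 mg/s;
* ``koivisto`` -- spray-coating exhaust (H = 3 m, dp = 280 nm,
  rho = 2100 kg/m3), yearly-average emission 3.5 ug/s, spray activity
  emission 0.33 mg/s;

both with U = 2.5 m/s, T = 288.15 K, hpbl = 1 km, Davidson curves, and
the default stability climatology for annual averaging.

The sweep grids reproduce the study design: 1296 combinations for
nanomaterials (size-resolved deposition) and 486 for a generic
pollutant with index-paired (vset, vdep) values.
"""

from __future__ import annotations

import itertools
import json
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd
import yaml

from .atmosphere import AtmosphericState, StabilityClass, get_scheme
from .deposition import BEYOND_DOMAIN, DepositionProfile
from .exposure import (
    SoilScenario,
    StabilityClimatology,
    nf_ff_concentrations,
    pec_pnec_ratio,
    pec_soil,
    weighted_average_flux,
)
from .particle import CanopyDeposition, FixedDeposition, ParticleSpec, VelocityModel
from .plume import PlumeModel, SourceSpec, default_grid

__all__ = [
    "Scenario",
    "SweepSpec",
    "ScenarioRun",
    "run_scenario",
    "run_sweep",
    "sweep_summary",
    "case_study",
    "enm_sweep",
    "generic_sweep",
    "mini_sweep",
    "generate_fixtures",
    "parse_config",
    "serialize_config",
]


# ---------------------------------------------------------------------------
# Units

_UNIT_FACTORS: dict[str, dict[str, float]] = {
    "emission": {"g/s": 1.0, "mg/s": 1e-3, "ug/s": 1e-6, "g/h": 1 / 3600.0, "mg/min": 1e-3 / 60.0},
    "length": {"m": 1.0, "km": 1e3, "cm": 1e-2},
    "diameter": {"nm": 1.0, "um": 1e3},
    "velocity": {"m/s": 1.0, "cm/s": 1e-2, "mm/s": 1e-3},
    "density": {"kg/m3": 1.0, "g/cm3": 1e3},
    "temperature": {"K": 1.0},
    "time": {"yr": 1.0},
    "soilconc": {"g/kg": 1.0, "mg/kg": 1e-3, "ug/kg": 1e-6},
}

_QTY_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*([A-Za-z/0-9]*)\s*$")


def _parse_qty(value, kind: str, default_unit: str) -> float:
    """Parse '29 ug/s' / 29.0 / '29' into the SI value for ``kind``."""
    factors = _UNIT_FACTORS[kind]
    if isinstance(value, (int, float)):
        return float(value) * factors[default_unit]
    m = _QTY_RE.match(str(value))
    if not m:
        raise ValueError(f"cannot parse quantity {value!r}")
    num, unit = float(m.group(1)), m.group(2) or default_unit
    if unit not in factors:
        raise ValueError(f"unknown unit {unit!r} for {kind} (allowed: {sorted(factors)})")
    return num * factors[unit]


def _fmt_qty(si_value: float, kind: str, unit: str) -> str:
    v = si_value / _UNIT_FACTORS[kind][unit]
    return f"{v:.10g} {unit}"


# ---------------------------------------------------------------------------
# Scenario


@dataclass(frozen=True)
class Scenario:
    """A fully specified dispersion/deposition run (SI units internally)."""

    name: str
    source: SourceSpec
    U: float
    T: float
    hpbl: float
    scheme: str = "davidson"
    stability: tuple[str, ...] = ("d",)
    particle: ParticleSpec | None = None
    fixed: FixedDeposition | None = None
    deposition: VelocityModel | None = None  # defaults to CanopyDeposition
    climatology: StabilityClimatology | None = None
    x_min: float = 10.0
    x_max: float = 500_000.0
    points_per_decade: int = 50
    soil: SoilScenario | None = None

    def __post_init__(self) -> None:
        if (self.particle is None) == (self.fixed is None):
            raise ValueError("exactly one of particle / fixed velocities must be given")
        object.__setattr__(
            self, "stability", tuple(StabilityClass.coerce(s).value for s in self.stability)
        )

    def velocity_model(self) -> VelocityModel:
        if self.fixed is not None:
            return self.fixed
        return self.deposition or CanopyDeposition()

    def grid(self) -> np.ndarray:
        return default_grid(self.x_min, self.x_max, self.points_per_decade)

    def atmosphere(self, stability: str) -> AtmosphericState:
        return AtmosphericState(
            U=self.U, T=self.T, hpbl=self.hpbl, stability=stability, scheme=get_scheme(self.scheme)
        )

    def with_emission(self, E: float, name: str | None = None) -> "Scenario":
        return replace(self, source=SourceSpec(E, self.source.H), name=name or self.name)


# -- config (de)serialization ----------------------------------------------


def parse_config(cfg: Mapping) -> Scenario:
    """Build a Scenario from a (YAML-loaded) mapping with unit strings."""
    try:
        src = cfg["source"]
        atmo = cfg["atmosphere"]
    except KeyError as exc:
        raise ValueError(f"config missing required section: {exc}") from exc
    source = SourceSpec(
        E=_parse_qty(src["emission"], "emission", "ug/s"),
        H=_parse_qty(src["height"], "length", "m"),
    )
    particle = fixed = None
    if "particle" in cfg and cfg["particle"] is not None:
        p = cfg["particle"]
        particle = ParticleSpec(
            dp=_parse_qty(p["diameter"], "diameter", "nm"),
            rho=_parse_qty(p["density"], "density", "kg/m3"),
        )
    if "velocities" in cfg and cfg["velocities"] is not None:
        v = cfg["velocities"]
        fixed = FixedDeposition(
            vset=_parse_qty(v["vset"], "velocity", "cm/s"),
            vdep=_parse_qty(v["vdep"], "velocity", "cm/s"),
        )
    stability = atmo.get("stability", "d")
    if isinstance(stability, str):
        stability = [s.strip() for s in stability.split(",")] if "," in stability else [stability]
    clim = None
    if cfg.get("climatology") == "default":
        clim = StabilityClimatology()
    elif isinstance(cfg.get("climatology"), Mapping):
        clim = StabilityClimatology(dict(cfg["climatology"]))
    soil = None
    if isinstance(cfg.get("soil"), Mapping):
        s = cfg["soil"]
        soil = SoilScenario(
            Hsoil=_parse_qty(s.get("depth", "0.05 m"), "length", "m"),
            rho_soil=_parse_qty(s.get("density", "1500 kg/m3"), "density", "kg/m3"),
            years=_parse_qty(s.get("years", 100), "time", "yr"),
            pnec_g_kg=_parse_qty(s.get("pnec", "1000 ug/kg"), "soilconc", "ug/kg"),
        )
    dom = cfg.get("domain", {})
    return Scenario(
        name=str(cfg.get("name", "scenario")),
        source=source,
        particle=particle,
        fixed=fixed,
        U=_parse_qty(atmo["wind"], "velocity", "m/s"),
        T=_parse_qty(atmo["temperature"], "temperature", "K"),
        hpbl=_parse_qty(atmo["hpbl"], "length", "km"),
        scheme=str(atmo.get("scheme", "davidson")).lower(),
        stability=tuple(stability),
        climatology=clim,
        x_min=_parse_qty(dom.get("x_min", "10 m"), "length", "m"),
        x_max=_parse_qty(dom.get("x_max", "500 km"), "length", "km"),
        points_per_decade=int(dom.get("points_per_decade", 50)),
        soil=soil,
    )


def serialize_config(s: Scenario) -> dict:
    """Inverse of :func:`parse_config`; display units follow the input tables."""
    cfg: dict = {
        "name": s.name,
        "source": {
            "emission": _fmt_qty(s.source.E, "emission", "ug/s"),
            "height": _fmt_qty(s.source.H, "length", "m"),
        },
        "atmosphere": {
            "wind": _fmt_qty(s.U, "velocity", "m/s"),
            "temperature": _fmt_qty(s.T, "temperature", "K"),
            "hpbl": _fmt_qty(s.hpbl, "length", "km"),
            "scheme": s.scheme,
            "stability": ",".join(s.stability),
        },
        "domain": {
            "x_min": _fmt_qty(s.x_min, "length", "m"),
            "x_max": _fmt_qty(s.x_max, "length", "km"),
            "points_per_decade": s.points_per_decade,
        },
    }
    if s.particle is not None:
        cfg["particle"] = {
            "diameter": _fmt_qty(s.particle.dp, "diameter", "nm"),
            "density": _fmt_qty(s.particle.rho, "density", "kg/m3"),
        }
    if s.fixed is not None:
        cfg["velocities"] = {
            "vset": _fmt_qty(s.fixed.vset, "velocity", "cm/s"),
            "vdep": _fmt_qty(s.fixed.vdep, "velocity", "cm/s"),
        }
    if s.climatology is not None:
        cfg["climatology"] = (
            "default" if s.climatology.P == StabilityClimatology().P else dict(s.climatology.P)
        )
    if s.soil is not None:
        cfg["soil"] = {
            "depth": _fmt_qty(s.soil.Hsoil, "length", "m"),
            "density": _fmt_qty(s.soil.rho_soil, "density", "kg/m3"),
            "years": s.soil.years,
            "pnec": _fmt_qty(s.soil.pnec_g_kg, "soilconc", "ug/kg"),
        }
    return cfg


def load_scenario(path) -> Scenario:
    with open(path) as fh:
        return parse_config(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# Running


@dataclass
class ScenarioRun:
    """Results of one scenario: JSON-ready report plus in-memory profiles."""

    scenario: Scenario
    report: dict
    solutions: dict
    profiles: dict

    def report_json(self) -> str:
        return json.dumps(self.report, indent=2, sort_keys=True)


def _x50_json(x50: float):
    return "beyond_domain" if np.isinf(x50) else float(x50)


def run_scenario(s: Scenario) -> ScenarioRun:
    """Solve the mass-balance-corrected plume for every stability class of a
    scenario and assemble the run report (max concentrations, x50, NF/FF,
    PECsoil)."""
    grid = s.grid()
    vel = s.velocity_model().velocities(s.particle, s.T)
    solutions, profiles, per_class = {}, {}, {}
    for cls in s.stability:
        sol = PlumeModel(s.source, s.atmosphere(cls), vel).solve(grid)
        prof = DepositionProfile.from_solution(sol)
        solutions[cls], profiles[cls] = sol, prof
        cmax, xmax = sol.max_ground()
        per_class[cls] = {
            "cmax_ug_m3": cmax * 1e6,
            "x_at_max_m": xmax,
            "x50_m": _x50_json(prof.x50),
            "fdep_at_xtot": float(prof.fdep[-1]),
            "mass_balance_worst_residual": float(np.max(np.abs(1 - sol.fdep - sol.fsusp))),
        }
    worst_cls = max(per_class, key=lambda c: per_class[c]["cmax_ug_m3"])
    report = {
        "scenario": s.name,
        "inputs": serialize_config(s),
        "velocities_m_s": {"vset": vel.vset, "vdep": vel.vdep},
        "grid": {"n_points": int(grid.size), "x_min_m": float(grid[0]), "x_max_m": float(grid[-1])},
        "per_class": per_class,
        "worst_case": {
            "stability": worst_cls,
            "cmax_ug_m3": per_class[worst_cls]["cmax_ug_m3"],
            "x_at_max_m": per_class[worst_cls]["x_at_max_m"],
        },
    }

    # Climatology-weighted annual-average quantities (flux-based, per the
    # annual-average deposition definition) when all six classes were run.
    favg = None
    if s.climatology is not None and len(s.stability) == 6:
        fluxes = {c: profiles[c].flux for c in s.stability}
        favg = weighted_average_flux(fluxes, s.climatology)
        fdep_w = weighted_average_flux({c: profiles[c].fdep for c in s.stability}, s.climatology)
        from .deposition import x50_from_arrays

        x50_w = x50_from_arrays(grid, fdep_w)
        i = int(np.argmax(favg))
        report["weighted"] = {
            "favg_max_g_m2_s": float(favg[i]),
            "x_at_favg_max_m": float(grid[i]),
            "fdep_at_xtot": float(fdep_w[-1]),
            "x50_m": _x50_json(x50_w),
        }
        if np.isfinite(x50_w) and 0 < x50_w < s.x_max and vel.vdep > 0:
            nf = nf_ff_concentrations(s.source.E, vel.vdep, x50_w, s.x_max)
            report["nf_ff"] = {"CN_g_m3": nf.CN, "CF_g_m3": nf.CF, "x50_m": nf.x50, "xtot_m": nf.xtot}

    if s.soil is not None:
        flux_for_soil = favg if favg is not None else profiles[s.stability[0]].flux
        pec = pec_soil(flux_for_soil, s.soil)
        i = int(np.argmax(pec))
        report["soil"] = {
            "years": s.soil.years,
            "pec_soil_max_g_kg": float(pec[i]),
            "x_at_pec_max_m": float(grid[i]),
            "pec_pnec_ratio_max": float(pec_pnec_ratio(flux_for_soil[i], s.soil)),
            "pnec_g_kg": s.soil.pnec_g_kg,
        }
    return ScenarioRun(scenario=s, report=report, solutions=solutions, profiles=profiles)


# ---------------------------------------------------------------------------
# Case studies (source and particle values from the two TiO2 release reports)

_CASES = {
    "fonseca": dict(
        yearly=29e-6, activity=0.14e-3, H=7.8, dp=260.0, rho=940.0
    ),
    "koivisto": dict(
        yearly=3.5e-6, activity=0.33e-3, H=3.0, dp=280.0, rho=2100.0
    ),
}


def case_study(name: str, emission: str = "yearly") -> Scenario:
    """Built-in TiO2 release scenario; ``emission`` is 'yearly' or 'activity'."""
    try:
        c = _CASES[name.lower()]
    except KeyError:
        raise ValueError(f"unknown case study {name!r} (choose from {sorted(_CASES)})")
    if emission not in ("yearly", "activity"):
        raise ValueError("emission must be 'yearly' or 'activity'")
    return Scenario(
        name=f"{name.lower()}-{emission}",
        source=SourceSpec(E=c[emission], H=c["H"]),
        particle=ParticleSpec(dp=c["dp"], rho=c["rho"]),
        U=2.5,
        T=288.15,
        hpbl=1000.0,
        scheme="davidson",
        stability=("a", "b", "c", "d", "e", "f"),
        climatology=StabilityClimatology(),
        soil=SoilScenario(),
    )


# ---------------------------------------------------------------------------
# Sweeps


@dataclass(frozen=True)
class SweepSpec:
    """A cartesian sweep grid.

    ``velocity_pairs`` (generic mode) are index-paired (vset, vdep) in m/s:
    they expand together, not as a product.  ``particles`` (nanomaterial
    mode) cross diameters with densities and temperatures.
    """

    name: str
    E: float
    heights: tuple[float, ...]
    winds: tuple[float, ...]
    schemes: tuple[str, ...]
    hpbls: tuple[float, ...]
    classes: tuple[str, ...]
    temperatures: tuple[float, ...] = (288.15,)
    velocity_pairs: tuple[tuple[float, float], ...] = ()
    diameters: tuple[float, ...] = ()
    densities: tuple[float, ...] = ()
    x_max: float = 500_000.0
    points_per_decade: int = 50

    def __post_init__(self) -> None:
        if bool(self.velocity_pairs) == bool(self.diameters):
            raise ValueError("give either velocity_pairs or diameters/densities")

    @property
    def n_combinations(self) -> int:
        base = (
            len(self.heights)
            * len(self.winds)
            * len(self.schemes)
            * len(self.hpbls)
            * len(self.classes)
            * len(self.temperatures)
        )
        if self.velocity_pairs:
            return base * len(self.velocity_pairs)
        return base * len(self.diameters) * len(self.densities)

    def expand(self) -> Iterator[Scenario]:
        if self.velocity_pairs:
            part_axis = [("fixed", pair) for pair in self.velocity_pairs]
        else:
            part_axis = [
                ("particle", (dp, rho))
                for dp in self.diameters
                for rho in self.densities
            ]
        for (kind, pv), H, T, U, scheme, hpbl, cls in itertools.product(
            part_axis,
            self.heights,
            self.temperatures,
            self.winds,
            self.schemes,
            self.hpbls,
            self.classes,
        ):
            kw = dict(
                name=self.name,
                source=SourceSpec(self.E, H),
                U=U,
                T=T,
                hpbl=hpbl,
                scheme=scheme,
                stability=(cls,),
                x_max=self.x_max,
                points_per_decade=self.points_per_decade,
            )
            if kind == "fixed":
                kw["fixed"] = FixedDeposition(vset=pv[0], vdep=pv[1])
            else:
                kw["particle"] = ParticleSpec(dp=pv[0], rho=pv[1])
            yield Scenario(**kw)


def generic_sweep() -> SweepSpec:
    """Generic-pollutant grid: 486 combinations with index-paired (vset, vdep)."""
    return SweepSpec(
        name="generic",
        E=29e-6,
        heights=(2.0, 10.0, 50.0),
        velocity_pairs=((1e-6, 1e-4), (1e-4, 1e-3), (1e-3, 1e-2)),  # m/s
        winds=(1.0, 2.5, 10.0),
        schemes=("davidson", "klug"),
        hpbls=(200.0, 1000.0, 2000.0),
        classes=("a", "d", "f"),
    )


def enm_sweep() -> SweepSpec:
    """Nanomaterial grid: 1296 combinations with size-resolved deposition."""
    return SweepSpec(
        name="enm",
        E=29e-6,
        heights=(2.0, 50.0),
        diameters=(10.0, 100.0, 500.0),
        densities=(1000.0, 4230.0, 18000.0),
        temperatures=(243.15, 273.15, 303.15),
        winds=(1.0, 10.0),
        schemes=("davidson", "klug"),
        hpbls=(200.0, 2000.0),
        classes=("a", "d", "f"),
    )


def mini_sweep() -> SweepSpec:
    """Three-combination toy grid for fixtures and fast tests."""
    return SweepSpec(
        name="mini",
        E=29e-6,
        heights=(2.0,),
        velocity_pairs=((1e-4, 1e-3),),
        winds=(2.5,),
        schemes=("davidson",),
        hpbls=(1000.0,),
        classes=("a", "d", "f"),
        points_per_decade=20,
    )


def run_sweep(spec: SweepSpec, progress: bool = False) -> pd.DataFrame:
    """Run every combination; one tidy row per combination.

    Columns: the swept inputs plus vset/vdep actually used, the maximum
    ground-level centerline concentration and its distance, x50 (inf when
    beyond the domain) and fdep at the domain edge.
    """
    rows = []
    it = spec.expand()
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm

        it = tqdm(it, total=spec.n_combinations)
    for sc in it:
        run = _run_single(sc)
        rows.append(run)
    df = pd.DataFrame(rows)
    assert len(df) == spec.n_combinations
    return df


def _run_single(sc: Scenario) -> dict:
    vel = sc.velocity_model().velocities(sc.particle, sc.T)
    cls = sc.stability[0]
    sol = PlumeModel(sc.source, sc.atmosphere(cls), vel).solve(sc.grid())
    prof = DepositionProfile.from_solution(sol)
    cmax, xmax = sol.max_ground()
    return {
        "E_g_s": sc.source.E,
        "H_m": sc.source.H,
        "dp_nm": sc.particle.dp if sc.particle else np.nan,
        "rho_kg_m3": sc.particle.rho if sc.particle else np.nan,
        "T_K": sc.T,
        "U_m_s": sc.U,
        "scheme": sc.scheme,
        "hpbl_m": sc.hpbl,
        "stability": cls,
        "vset_m_s": vel.vset,
        "vdep_m_s": vel.vdep,
        "cmax_g_m3": cmax,
        "x_at_max_m": xmax,
        "x50_m": prof.x50,
        "fdep_at_xtot": float(prof.fdep[-1]),
    }


def sweep_summary(df: pd.DataFrame) -> pd.DataFrame:
    """Per-parameter median/quartile table of x50 (sensitivity overview)."""
    rows = []
    finite = df.assign(x50_m=df["x50_m"].replace(np.inf, np.nan))
    for col in ("H_m", "dp_nm", "U_m_s", "scheme", "hpbl_m", "stability", "vdep_m_s"):
        if col not in df or df[col].isna().all():
            continue
        for value, grp in finite.groupby(col, dropna=True):
            q = grp["x50_m"].quantile([0.25, 0.5, 0.75])
            rows.append(
                {
                    "parameter": col,
                    "value": value,
                    "n": len(grp),
                    "n_beyond_domain": int(np.isinf(df.loc[grp.index, "x50_m"]).sum()),
                    "x50_q25_m": q.loc[0.25],
                    "x50_median_m": q.loc[0.5],
                    "x50_q75_m": q.loc[0.75],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Fixtures


def generate_fixtures(seed: int = 0, outdir=None) -> dict:
    """Packaged toy scenarios for tests and demos.

    Returns (and optionally writes as YAML under ``outdir``):

    * the two case-study configs,
    * the three-point mini sweep,
    * a synthetic constant-vdep scenario in the well-mixed regime whose
      conditional depletion has the closed form
      (1-fdep(x2))/(1-fdep(x1)) = exp(-vdep*(x2-x1)/(U*hpbl)).

    The model is deterministic; ``seed`` is recorded for toys that may add
    observation noise on top of the fixtures.
    """
    wellmixed = Scenario(
        name="wellmixed-analytic",
        source=SourceSpec(E=29e-6, H=2.0),
        fixed=FixedDeposition(vset=0.0, vdep=1e-3),
        U=1.0,
        T=288.15,
        hpbl=200.0,
        scheme="klug",
        stability=("a",),
        x_max=100_000.0,
    )
    fixtures = {
        "fonseca": case_study("fonseca"),
        "koivisto": case_study("koivisto"),
        "mini_sweep": mini_sweep(),
        "wellmixed": wellmixed,
        "seed": int(seed),
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for key in ("fonseca", "koivisto", "wellmixed"):
            with open(outdir / f"{key}.yaml", "w") as fh:
                yaml.safe_dump(serialize_config(fixtures[key]), fh, sort_keys=True)
    return fixtures
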