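# nanoplume

Atmospheric dispersion and dry-deposition modelling for engineered
nanomaterials (ENMs) released from a continuous point source — stack
emissions from a nanomaterial production or handling facility — with a
screening layer that turns the plume into local/regional exposure
estimates (airborne PEC, soil PEC, PEC/PNEC risk ratios).

Regional multimedia fate models mix an emission uniformly into a
~500 km box, which hides the concentration and deposition hot spot near
the source. `nanoplume` resolves that hot spot with an analytical plume
model and proposes the distance at which half the emitted mass has
deposited, **x50**, as the boundary between the local (near-field) and
regional (far-field) exposure compartments. It is aimed at
environmental and occupational exposure assessors doing screening-level
risk work on nanomaterials and other depositing aerosols.

## Model

Ground-level concentration of a plume from a source of strength E (g/s)
at height H, wind speed U, with Pasquill-stability dispersion widths
σ<sub>y</sub>(x), σ<sub>z</sub>(x) (Klug or Davidson parametrizations,
σ<sub>z</sub> capped at 5000 m):

* **classic** — Gaussian plume with ground reflection (non-depositing gas);
* **ermak** — Ermak's analytical solution for a plume depositing at
  velocity v<sub>dep</sub> while settling at v<sub>set</sub>, in Rao's
  simplified form with K<sub>z</sub> = Uσ<sub>z</sub>²/2x and the
  erfc depletion term in ξ = (z+H)/(√2 σ<sub>z</sub>) + v₀σ<sub>z</sub>/(√2 K<sub>z</sub>),
  v₀ = v<sub>dep</sub> − ½v<sub>set</sub>;
* **rao** — the same with boundary-layer reflections: image sources at
  effective heights |H + 2j·H<sub>pbl</sub>|, j = −10…10;
* **rao_mass_balanced** (default) — the reflected solution rescaled per
  downwind distance so that deposited + suspended mass fractions close:
  f<sub>dep</sub>(x) + f<sub>susp</sub>(x) = 1 within 1%.

Particle velocities follow Stokes settling with Cunningham slip,
v<sub>set</sub> = gρC<sub>c</sub>d<sub>p</sub>²/18η, and a resistance
model v<sub>dep</sub> = v<sub>set</sub> + 1/(r<sub>a</sub>+r<sub>c</sub>)
whose canopy term combines Brownian (Sc<sup>−2/3</sup>) and
interception collection — minimum deposition velocity near 100 nm,
with 10 nm particles depositing about 10× faster.

Downstream quantities: deposition flux F = v<sub>dep</sub>·C(x,y,2 m);
cumulative deposited fraction f<sub>dep</sub>(x) and the **x50**
distance; near-/far-field compartment concentrations
C<sub>N</sub> = E/(2π x50² v<sub>dep</sub>),
C<sub>F</sub> = E/(2π (x<sub>tot</sub>²−x50²) v<sub>dep</sub>); and soil
accumulation PEC<sub>soil</sub> = F<sub>avg</sub>·a·365·24·3600/(H<sub>soil</sub>ρ<sub>soil</sub>)
with a stability-climatology-weighted annual flux F<sub>avg</sub>.

## Worked example

Two built-in TiO2 release case studies are included: a paint-factory
stack (`fonseca`) and a spray-coating exhaust (`koivisto`). Running

```
nanoplume case-study koivisto
```

solves the corrected plume for all six stability classes (E = 3.5 μg/s,
H = 3 m, d<sub>p</sub> = 280 nm, ρ = 2100 kg/m³, U = 2.5 m/s,
H<sub>pbl</sub> = 1 km, Davidson curves) and prints a JSON report whose
key entries are:

```json
{
  "worst_case": {
    "cmax_ug_m3": 0.09569368423062515,
    "stability": "d",
    "x_at_max_m": 13.181769167917993
  },
  "weighted": {
    "favg_max_g_m2_s": 6.234769146358644e-11,
    "x_at_favg_max_m": 20.88958790619678,
    "fdep_at_xtot": 0.39542095804603805,
    "x50_m": "beyond_domain"
  },
  "soil": {
    "years": 100.0,
    "pec_soil_max_g_kg": 0.0026215957306608825,
    "pec_pnec_ratio_max": 2.6215957306608826,
    "pnec_g_kg": 0.001
  }
}
```

Reading: the worst-case ground-level (z = 2 m) concentration is about
0.1 μg/m³, reached 13 m downwind in a neutral atmosphere (class d) —
three orders of magnitude below the occupational recommended exposure
limit for ultrafine TiO2. Less than half of the emission deposits
within 500 km (`x50_m: beyond_domain`), so most of the material leaves
the regional domain airborne. Nevertheless, a century of continuous
deposition at the annual-average flux peak (≈6×10⁻¹¹ g/m²/s, 21 m from
the stack) would accumulate ≈2.6 mg TiO2 per kg of topsoil — about 2.6×
the soil predicted-no-effect concentration — but only in the immediate
vicinity of the facility.

Other entry points: `nanoplume run config.yaml` (YAML scenarios with
unit strings such as `emission: 0.51 g/h`), `nanoplume x50`,
`nanoplume sweep generic|enm`, `nanoplume fixtures`, or the library API
(`nanoplume.PlumeModel`, `nanoplume.run_scenario`, ...).

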