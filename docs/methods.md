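# Methods

## Scope and model family

`nanoplume` computes steady-state concentration and deposition fields
for a single continuous point source in a horizontally homogeneous
boundary layer. The transport core is the analytical Gaussian-plume
family: dispersion is parametrized by Pasquill stability class rather
than resolved turbulence, the wind is constant and along x, and the
terrain is flat. Aerosol dynamics (coagulation, condensation growth),
wet deposition, resuspension, plume rise, building wakes and multiple
sources are out of scope; particle size enters only through the
settling and dry-deposition velocities.

## Dispersion parameters

Two σ-parametrizations are shipped as packaged CSV tables with
per-coefficient source annotations:

* **Klug (1969)** power laws σ = R·x^r (x in m), transcribed from
  Seinfeld & Pandis, *Atmospheric Chemistry and Physics*, Table 18.3;
* **Davidson (1990)** modified power laws σ = a·x^(b + c·ln x) (x in
  km), from Davidson, *JAWMA* 40:1146.

All public interfaces take x in metres; the km conversion is internal
to the Davidson scheme. σ<sub>z</sub> is capped at 5000 m — without the
cap the unstable-class exponents grow without bound. Two known fit
artifacts of the Davidson quadratic-in-ln(x) exponent are documented
rather than patched, because the published coefficients are used
verbatim: class-a σ<sub>z</sub> has a spurious shallow minimum near
x ≈ 16 m (≈6% dip relative to 10 m), and class-f σ<sub>z</sub> peaks
near 461 km and rolls off by <0.1% at the 500 km domain edge. The
monotonicity tests therefore check Davidson curves from 100 m (the
range the fits target) with 0.1% relative slack. Evaluation below
x = 10 m is rejected; 10 m is the default grid minimum.

## Particle velocities

Settling: Stokes' law with the Allen–Raabe slip correction
C<sub>c</sub> = 1 + Kn(1.257 + 0.4·e^(−1.1/Kn)), mean free path 66.4 nm
at 293.15 K / 101 325 Pa scaled with temperature and pressure, and
Sutherland viscosity η(T) = 1.458×10⁻⁶·T^1.5/(T+110.4).

Dry deposition is pluggable, with three modes:

* **fixed** — (v<sub>set</sub>, v<sub>dep</sub>) are direct inputs
  (generic-pollutant sweeps use index-paired values);
* **canopy resistance** — v<sub>dep</sub> = v<sub>set</sub> +
  1/(r<sub>a</sub> + r<sub>c</sub>) with
  r<sub>c</sub> = 1/(u\*·(Sc^(−2/3) + d<sub>p</sub>/L)). Defaults:
  u\* = 0.3 m/s, r<sub>a</sub> = 50 s/m, effective interception scale
  L = 100 μm. These were calibrated once against the published
  behaviour of nanoparticle dry deposition over a pine forest: a
  minimum near 100–150 nm, roughly 0.05–0.5 cm/s across 10–500 nm, a
  10 nm/100 nm velocity ratio of ≈8 (field value "about ten"), and —
  as an independent closure check — v<sub>dep</sub>(280 nm) ≈ 0.09 cm/s,
  consistent with the ≈0.1 cm/s implied by combining the reported
  20% deposited-within-500-km figure for the spray-coating case with
  the well-mixed depletion law f<sub>susp</sub> ≈ exp(−v<sub>dep</sub>x/UH<sub>pbl</sub>).
  L is an aggregate of canopy fine structure, not a literal needle
  diameter. The calibration was fixed before the validation suite was
  run and is not a tuning knob;
* **lookup table** — log-linear interpolation of user (d<sub>p</sub>,
  v<sub>dep</sub>) pairs from CSV.

## Plume formulations and numerics

The depositing solution follows Ermak in Rao's simplified form, with
K<sub>z</sub> = Uσ<sub>z</sub>²/2x, v₀ = v<sub>dep</sub> − ½v<sub>set</sub>
and ξ = (z+H)/(√2σ<sub>z</sub>) + v₀σ<sub>z</sub>/(√2K<sub>z</sub>);
the √2 factors are required for the erfc term to reproduce Ermak's
solution and for the v<sub>dep</sub> = v<sub>set</sub> = 0 limit to
collapse exactly to the classic plume (asserted at machine precision in
the tests). Boundary-layer reflection adds image sources at
|H + 2j·H<sub>pbl</sub>| for j = −10…10; the absolute value makes
ground images deposit and lid images reflect cleanly, and truncation at
|j| = 10 is verified to agree with |j| = 50 within 1% at ground level.

Numerical choices:

* exp(ξ²)·erfc(ξ) is evaluated as `scipy.special.erfcx`; all Gaussian
  exponents are combined analytically before exponentiation, so the
  field is finite even when σ<sub>z</sub> is centimetres;
* tiny negative values from cancellation in the image sum are clamped
  to zero with a warning;
* the downwind grid is geometric, 50 points per decade from 10 m to
  500 km (≈236 points); reported arg-max distances are grid-resolved.

## Mass-balance correction

The raw reflected solution over-conserves near the source (deposited +
suspended fractions reach 1.2–1.4 in strongly depositing cases, in line
with the ~20% ground-level bias reported for the uncorrected solution
in the literature). The correction rescales the field per distance by
1/(f<sub>dep</sub>(x)+f<sub>susp</sub>(x)), marching downwind so the
cumulative deposition integral always uses already-corrected upstream
flux. Because the residual at a grid point is linear in the local
factor, each point is solved in closed form within the sweep; the
iteration loop (cap 100, diagnostic error with the worst-x residual on
failure) converges to |1 − f<sub>dep</sub> − f<sub>susp</sub>| ≲ 10⁻⁹
in one pass, far inside the 1% tolerance.

f<sub>susp</sub>(x) integrates the crosswind-integrated horizontal flux
vertically over [0, H<sub>pbl</sub>]: with image sources the lid folds
all suspended mass into the layer, so the layer integral is the
physically meaningful one even though the defining integral is often
written to ∞. The quadrature uses per-distance node sets that resolve
both the layer (81 uniform nodes) and the thin plume (nodes clustered
within ±8σ<sub>z</sub> of the source height and at both boundaries),
trapezoid-summed; the v<sub>dep</sub> = 0 conservation check holds to
~0.3%. The crosswind integral in the deposition rate is analytic
(√(2π)σ<sub>y</sub> × centerline), and the downwind integral is
trapezoid on the log grid.

x50 is interpolated log-linearly in x between the grid points
bracketing f<sub>dep</sub> = 0.5 (f<sub>dep</sub> is close to a power
law on the log grid) and reported as infinity ("beyond domain") when
f<sub>dep</sub>(500 km) < 0.5.

## Exposure layer

Ground level means z = 2 m by convention (configurable). Deposition
flux magnitudes are v<sub>dep</sub>·C(x, y, 2 m). Annual averages
weight per-class profiles with a stability climatology (default:
northern-hemisphere combined day/night frequencies 4/4/4/37/25.5/25.5%
for classes a–f). PEC<sub>soil</sub> accumulates the flux into a
uniform 0.05 m, 1500 kg/m³ topsoil layer over a 365-day year, evaluated
on the plume centerline — a fixed-wind-direction worst case appropriate
for screening, not a wind-rose average. PNEC defaults are packaged
(nano-TiO2 1000 μg/kg, CNT 176 μg/kg). The NF/FF compartment
concentrations use the steady-state closed forms; the NF→FF transfer
rate needed by multicompartment couplings is deliberately an interface
stub, because the closed forms cover the screening use case and a
guessed rate expression would be unverifiable here.

## Synthetic scenarios and what the tests show

The sweep grids and case-study inputs are the study conditions
themselves (printed parameter tables), not randomized synthetic data;
the model is deterministic. The fixture generator adds a constant-vdep
scenario placed in the fully mixed regime (Klug class a,
H<sub>pbl</sub> = 200 m), where conditional depletion has the closed
form exp(−v<sub>dep</sub>Δx/UH<sub>pbl</sub>); the model matches it to
~10⁻⁵, validating the whole flux/fraction pipeline independently of the
plume details. What passing tests do **not** show: agreement with field
measurements of real ENM plumes (no such dataset is bundled), behaviour
in low-wind or complex-terrain conditions where Gaussian models are
known to degrade, or the accuracy of the canopy deposition curve
outside 10–500 nm.

## Known limitations and open comparisons

* The canopy-model constants are a calibrated stand-in for the
  measurement-based curve they emulate; concentration-level results are
  accurate only to the factor that v<sub>dep</sub> is.
* A published large-particle benchmark (v<sub>dep</sub> = v<sub>set</sub> =
  10 cm/s, H = 30 m, U = 5 m/s) is reproduced closely for stable
  classes (x50 ≈ 1.55–1.66 km vs ≈1.5 km) but gives x50 ≈ 1.9 km for
  neutral conditions where the original reports ≈5.3 km; the original
  used different dispersion coefficients and no mass-balance
  correction, and the corresponding validation test documents this gap
  rather than hiding it.
* Minimum-x50 figures from the big sweeps are sensitive to the
  correction semantics and the v<sub>dep</sub> calibration; the
  uncorrected profile would cross f<sub>dep</sub> = 0.5 roughly a
  factor of two earlier in the strongly depositing corner of the grid.
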