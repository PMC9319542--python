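"""Plume formulations: symmetry, conservation, limits, reflections, correction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad

from nanoplume.atmosphere import AtmosphericState
from nanoplume.particle import FixedDeposition
from nanoplume.plume import (
    SQRT2PI,
    PlumeModel,
    SourceSpec,
    concentration_classic,
    concentration_ermak,
    concentration_rao,
    default_grid,
)

ATM_D = AtmosphericState(U=2.5, T=288.15, hpbl=1000.0, stability="d", scheme="davidson")
SRC = SourceSpec(29e-6, 7.8)
NO_DEP = FixedDeposition(0.0, 0.0).velocities()
DEP = FixedDeposition(1e-3, 1e-2).velocities()


def test_crosswind_symmetry_and_decay():
    x, z = 500.0, 2.0
    for y in (0.0, 10.0, 120.0):
        assert concentration_classic(x, y, z, SRC, ATM_D) == concentration_classic(
            x, -y, z, SRC, ATM_D
        )
    assert concentration_classic(x, 1e5, z, SRC, ATM_D) < 1e-30


@pytest.mark.parametrize("x", [100.0, 2000.0])
def test_classic_flux_conservation(x):
    """The horizontal mass flux U * integral(C) dy dz through any plane equals
    the emission rate (quadrature over z with the image mass, analytic in y)."""
    sigy = float(ATM_D.sigma_y(x))
    integral_z = quad(lambda z: concentration_classic(x, 0.0, z, SRC, ATM_D), 0, np.inf, limit=200)[0]
    flux = ATM_D.U * SQRT2PI * sigy * integral_z
    assert flux == pytest.approx(SRC.E, rel=1e-3)


def test_ermak_reduces_to_classic_without_deposition():
    x = np.geomspace(20.0, 2e5, 50)
    ce = concentration_ermak(x, 5.0, 3.0, SRC, ATM_D, NO_DEP)
    cc = concentration_classic(x, 5.0, 3.0, SRC, ATM_D)
    np.testing.assert_allclose(ce, cc, rtol=1e-14)


def test_deposition_depletes_far_field():
    x = np.geomspace(1e4, 5e5, 30)
    with_dep = concentration_ermak(x, 0.0, 2.0, SRC, ATM_D, DEP)
    without = concentration_classic(x, 0.0, 2.0, SRC, ATM_D)
    assert np.all(with_dep <= without + 1e-30)
    assert with_dep[-1] < 0.5 * without[-1]


@settings(max_examples=60, derandomize=True, deadline=None)
@given(
    x=st.floats(10.0, 5e5),
    y=st.floats(-500.0, 500.0),
    z=st.floats(0.0, 1000.0),
)
def test_concentrations_nonnegative(x, y, z):
    assert concentration_ermak(x, y, z, SRC, ATM_D, DEP) >= 0.0
    assert concentration_rao(x, y, z, SRC, ATM_D, DEP) >= 0.0


def _yamartino(x, y, z, src, atm, jmax=60):
    """Independent reflecting-lid image sum (no deposition), coded directly."""
    sy, sz = atm.sigma_y(x), atm.sigma_z(x)
    tot = 0.0
    for j in range(-jmax, jmax + 1):
        for sgn in (1.0, -1.0):
            h = sgn * src.H + 2.0 * j * atm.hpbl
            tot = tot + np.exp(-0.5 * ((z - h) / sz) ** 2)
    return src.E / (2 * np.pi * atm.U * sy * sz) * np.exp(-0.5 * (y / sy) ** 2) * tot


def test_rao_matches_yamartino_without_deposition():
    x = np.geomspace(10.0, 5e5, 40)
    got = concentration_rao(x, 0.0, 2.0, SRC, ATM_D, NO_DEP, j_max=10)
    want = _yamartino(x, 0.0, 2.0, SRC, ATM_D)
    np.testing.assert_allclose(got, want, rtol=1e-12)


def test_well_mixed_limit():
    """Far downwind with vdep = 0 the layer is uniformly mixed:
    C -> E / (sqrt(2 pi) sigma_y U hpbl), independent of z."""
    atm_a = AtmosphericState(U=2.5, T=288.15, hpbl=1000.0, stability="a", scheme="davidson")
    x = 2e5
    assert float(atm_a.sigma_z(x)) >= 5 * atm_a.hpbl
    want = SRC.E / (SQRT2PI * float(atm_a.sigma_y(x)) * atm_a.U * atm_a.hpbl)
    for z in (0.0, 250.0, 500.0, 990.0):
        got = float(concentration_rao(x, 0.0, z, SRC, atm_a, NO_DEP))
        assert got == pytest.approx(want, rel=0.02)


def test_reflection_truncation_converged_at_ten():
    x = np.geomspace(10.0, 5e5, 60)
    c10 = concentration_rao(x, 0.0, 2.0, SRC, ATM_D, DEP, j_max=10)
    c50 = concentration_rao(x, 0.0, 2.0, SRC, ATM_D, DEP, j_max=50)
    assert np.max(np.abs(c10 - c50) / np.max(c50)) < 0.01


def test_linearity_in_emission_rate():
    sol1 = PlumeModel(SRC, ATM_D, DEP).solve()
    sol2 = PlumeModel(SourceSpec(2 * SRC.E, SRC.H), ATM_D, DEP).solve()
    np.testing.assert_allclose(sol2.conc_ground, 2 * sol1.conc_ground, rtol=1e-12)
    assert sol1.max_ground()[1] == sol2.max_ground()[1]
    np.testing.assert_allclose(sol2.fdep, sol1.fdep, rtol=1e-12)


def test_formulations_agree_near_source():
    """Before the plume feels the lid (sigma_z < hpbl/10), and for
    nanoparticle-scale deposition velocities, all formulations agree
    within 5% (little mass has yet been lost or reflected)."""
    x = 200.0
    assert float(ATM_D.sigma_z(x)) < ATM_D.hpbl / 10
    vel = FixedDeposition(1e-4, 1e-3).velocities()
    vals = [
        float(concentration_classic(x, 0.0, 2.0, SRC, ATM_D)),
        float(concentration_ermak(x, 0.0, 2.0, SRC, ATM_D, vel)),
        float(concentration_rao(x, 0.0, 2.0, SRC, ATM_D, vel)),
    ]
    assert max(vals) / min(vals) < 1.05


def test_mass_balance_identity_and_near_unity_without_deposition():
    sol0 = PlumeModel(SRC, ATM_D, NO_DEP).solve()
    np.testing.assert_allclose(sol0.correction, 1.0, atol=5e-3)
    sol = PlumeModel(SRC, ATM_D, DEP).solve()
    np.testing.assert_allclose(sol.fdep + sol.fsusp, 1.0, atol=1e-9)


def test_correction_reduces_overpredicting_near_field(depositing_solution):
    """Where the raw series over-conserves (fdep + fsusp > 1) the corrected
    concentration must not exceed the uncorrected one."""
    sol = depositing_solution
    model = PlumeModel(sol.source, sol.atm, sol.vel, "rao")
    raw = model.solve(sol.x)
    over = (raw.fdep + raw.fsusp) > 1.0
    assert over.any()
    assert np.all(sol.conc_ground[over] <= raw.conc_ground[over] * (1 + 1e-9))


def test_ground_source_peaks_at_grid_minimum(depositing_solution):
    """An H = 2 m source evaluated at z = 2 m peaks at the first grid point."""
    _, xmax = depositing_solution.max_ground()
    assert xmax == depositing_solution.x[0] == 10.0


def test_input_validation():
    with pytest.raises(ValueError):
        concentration_classic(-1.0, 0.0, 2.0, SRC, ATM_D)
    with pytest.raises(ValueError):
        concentration_rao(100.0, 0.0, 2.0, SRC, ATM_D, DEP, j_max=0)
    with pytest.raises(ValueError):
        PlumeModel(SRC, ATM_D, DEP, model="gauss")
    with pytest.raises(ValueError):
        PlumeModel(SRC, ATM_D, DEP).solve(np.array([5.0, 4.0, 3.0]))
    with pytest.raises(ValueError):
        SourceSpec(0.0, 5.0)
    with pytest.raises(ValueError):
        default_grid(100.0, 10.0)
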