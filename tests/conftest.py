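import numpy as np
import pytest

from nanoplume import (
    AtmosphericState,
    DepositionProfile,
    FixedDeposition,
    PlumeModel,
    SourceSpec,
    case_study,
    default_grid,
    generic_sweep,
    run_scenario,
    run_sweep,
)


@pytest.fixture(scope="session")
def koivisto_run():
    """Spray-coating case study at the yearly-average emission rate."""
    return run_scenario(case_study("koivisto"))


@pytest.fixture(scope="session")
def fonseca_run():
    """Paint-factory case study at the yearly-average emission rate."""
    return run_scenario(case_study("fonseca"))


@pytest.fixture(scope="session")
def koivisto_activity_run():
    return run_scenario(case_study("koivisto", "activity"))


@pytest.fixture(scope="session")
def fonseca_activity_run():
    return run_scenario(case_study("fonseca", "activity"))


@pytest.fixture(scope="session")
def depositing_solution():
    """A strongly depositing stable-atmosphere plume used across tests."""
    vel = FixedDeposition(vset=1e-3, vdep=1e-2).velocities()
    atm = AtmosphericState(U=1.0, T=288.15, hpbl=1000.0, stability="f", scheme="davidson")
    return PlumeModel(SourceSpec(29e-6, 2.0), atm, vel).solve(default_grid())


@pytest.fixture(scope="session")
def depositing_profile(depositing_solution):
    return DepositionProfile.from_solution(depositing_solution)


@pytest.fixture(scope="session")
def generic_sweep_df():
    """The full 486-combination generic-pollutant sweep (runs once per session)."""
    return run_sweep(generic_sweep())
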