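"""Shared fixtures: benchmark systems and a production trajectory.

Sampling-based fixtures are session-scoped so the Metropolis runs are paid
once across the whole suite.
"""

from __future__ import annotations

import pytest

from reedsnet.eds_core import EDSParameters
from reedsnet.pipeline import (
    RebalanceSettings,
    choose_s_ladder,
    harmonic_offset_increment,
    initial_offsets,
    rebalancing_loop,
)
from reedsnet.sampler import run_re_eds
from reedsnet.toy_model import (
    EndStateSystem,
    SiteSpec,
    ThermoConditions,
    Well,
    get_benchmark,
)


@pytest.fixture(scope="session")
def uncoupled_pair():
    return get_benchmark("uncoupled-3site")


@pytest.fixture(scope="session")
def coupled_pair():
    return get_benchmark("coupled-3site")


@pytest.fixture(scope="session")
def two_state_system():
    """One site, water vs probe well: the smallest two-state system."""
    return EndStateSystem(
        [SiteSpec(1, Well(0.0, 25.0), Well(0.3, 100.0), Well(0.0, 10.0))],
        (),
        ThermoConditions(),
    )


@pytest.fixture(scope="session")
def harmonic_300k_system():
    """Single site, water k=1 -> probe k=4, negligible restraint, T=300 K.

    Closed-form dG = 0.5*kT*ln(4) = 1.7289 kJ/mol at kT = 2.4943 kJ/mol.
    """
    return EndStateSystem(
        [SiteSpec(1, Well(0.0, 1.0), Well(0.0, 4.0), Well(0.0, 1e-9))],
        (),
        ThermoConditions(300.0),
    )


def rebalanced_production(system, seed, intensity=0.75, n_phases=25, steps_per_phase=600):
    """Pipeline + production run; returns (params, s=1 trajectory)."""
    params0 = EDSParameters(
        choose_s_ladder(4, 0.05),
        initial_offsets(system.states, harmonic_offset_increment(system)),
    )
    pr = rebalancing_loop(
        system, params0, RebalanceSettings(intensity=intensity),
        n_phases=8, steps_per_phase=400, stride=2, seed=seed,
    )
    trajs, _ = run_re_eds(system, pr.params, n_phases, steps_per_phase, 1, seed=seed + 5)
    return pr.params, trajs[1.0]


@pytest.fixture(scope="session")
def coupled_pocket_run(coupled_pair):
    """Rebalanced parameters and production s=1 ensemble, coupled pocket."""
    return rebalanced_production(coupled_pair.pocket, seed=11)


@pytest.fixture(scope="session")
def uncoupled_pocket_run(uncoupled_pair):
    return rebalanced_production(uncoupled_pair.pocket, seed=13)
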