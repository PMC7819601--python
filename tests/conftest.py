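"""Shared fixtures: small lattices and session-cached scenario ensembles.

The scenario ensembles (statistical positioning, spacer-enzyme
condensation, positioning well, explicit exchange) are expensive, so they
are computed once per session at reduced replica counts and shared by the
property and acceptance tests.
"""

from __future__ import annotations

import numpy as np
import pytest

import nucleosim as ns
from nucleosim.scenarios import calibrated_equilibrium
from nucleosim.equilibrium import sample_equilibrium


@pytest.fixture(scope="session")
def std_lattice() -> ns.LatticeSpec:
    return ns.LatticeSpec()


@pytest.fixture(scope="session")
def small_lattice() -> ns.LatticeSpec:
    return ns.LatticeSpec(length_bp=1470, tss_index=700)


@pytest.fixture(scope="session")
def uniform_small_field(small_lattice) -> ns.EnergyField:
    return ns.EnergyField.uniform(small_lattice)


def _equilibrium_ensemble(enzyme_rate, depth, seed, n_replicas=6, t_end=1200.0):
    eff, mu = calibrated_equilibrium(
        enzyme_rate=enzyme_rate, positioning_depth=depth
    )
    protocol = ns.SimulationProtocol(
        n_replicas=n_replicas, t_end=t_end, burn_in=400.0,
        sample_interval=1.0, seed=seed,
    )
    return sample_equilibrium(eff, protocol, mu=mu)


@pytest.fixture(scope="session")
def barrier_only_ensemble():
    """Statistical positioning: promoter barrier, no enzymes."""
    return _equilibrium_ensemble(0.0, 0.0, seed=21)


@pytest.fixture(scope="session")
def spacer_ensemble():
    """Barrier + spacer enzymes (k = 0.16/s) via the effective attraction."""
    return _equilibrium_ensemble(0.16, 0.0, seed=22, t_end=1300.0)


@pytest.fixture(scope="session")
def spacer_slow_ensemble():
    """Barrier + slower spacer enzymes (k = 0.08/s)."""
    return _equilibrium_ensemble(0.08, 0.0, seed=25, n_replicas=4, t_end=1000.0)


@pytest.fixture(scope="session")
def well_fast_ensemble():
    """Barrier + positioning well (-2 kBT) + enzymes k = 0.16/s."""
    return _equilibrium_ensemble(0.16, -2.0, seed=23)


@pytest.fixture(scope="session")
def well_slow_ensemble():
    """Barrier + positioning well (-2 kBT) + enzymes k = 0.08/s."""
    return _equilibrium_ensemble(0.08, -2.0, seed=24, n_replicas=4, t_end=1000.0)


@pytest.fixture(scope="session")
def exchange_ensemble():
    """Explicit diffusion + enzymes + histone exchange at r_const = 0.1/s."""
    from nucleosim.scenarios import scenario_field

    field = scenario_field(barrier_height=25.0)
    model = ns.KineticModel(
        field=field, D=1.0, enzyme_rate=0.16, enzyme_range_bp=332,
        r_const=0.1, mu=0.0,
    )
    cal = ns.calibrate_mu(
        model, 0.88, tolerance=0.005, effective_length_bp=14400,
        protocol=ns.SimulationProtocol(
            n_replicas=2, t_end=600.0, burn_in=300.0, sample_interval=2.0,
            seed=1234,
        ),
    )
    model.mu = cal.mu
    # collective ordering near the NDR relaxes far slower than single-rod
    # turnover (~74 s); burn in for several hundred turnover times
    protocol = ns.SimulationProtocol(
        n_replicas=4, t_end=40000.0, burn_in=20000.0, sample_interval=4.0,
        seed=31,
    )
    return ns.run_simulation(model, protocol)
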