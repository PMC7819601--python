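"""Ready-made simulation scenarios (barrier / enzymes / well / exchange).

Bundles the recurring steps -- build the energy field, calibrate the
effective enzyme attraction, calibrate the chemical potential, run the
sampler -- behind single calls, with in-process caching of the two
calibrations so that sweeps (phase diagrams, rate scans) do not repeat
them per grid point.
"""

from __future__ import annotations

from functools import lru_cache

from .equilibrium import EffectiveModel, effective_pair_potential, sample_equilibrium
from .kinetics import SimulationProtocol, calibrate_mu
from .lattice import EnergyField, LatticeSpec, PairPotential, make_barrier, make_positioning

__all__ = [
    "scenario_field",
    "calibrated_equilibrium",
    "phase_point_ensemble",
    "DEFAULT_TARGET_DENSITY",
]

DEFAULT_TARGET_DENSITY = 0.88
_BARRIER_SUPPORT_BP = 300  # width of the default promoter barrier


def scenario_field(
    barrier_height: float = 25.0,
    positioning_depth: float = 0.0,
    lattice: LatticeSpec | None = None,
) -> EnergyField:
    """Uniform-affinity field with the standard barrier/positioning shapes."""
    lattice = lattice or LatticeSpec()
    barrier = (
        make_barrier(lattice, height=barrier_height) if barrier_height > 0 else None
    )
    positioning = (
        make_positioning(lattice, depth=positioning_depth)
        if positioning_depth < 0
        else None
    )
    return EnergyField.uniform(lattice, barrier=barrier, positioning=positioning)


@lru_cache(maxsize=32)
def _cached_calibration(
    enzyme_rate: float,
    barrier_height: float,
    positioning_depth: float,
    target_density: float,
) -> tuple[tuple[float, ...], float]:
    """(u_eff table, mu) for a standard-lattice scenario."""
    field = scenario_field(barrier_height, positioning_depth)
    foot = field.lattice.footprint_bp
    table, _ = effective_pair_potential(enzyme_rate, footprint_bp=foot)
    pair = PairPotential(hard_core_bp=foot, effective_attraction=table)
    eff = EffectiveModel(field=field, pair=pair, enzyme_rate=enzyme_rate)
    free_length = field.lattice.length_bp - (
        _BARRIER_SUPPORT_BP if barrier_height > 0 else 0
    )
    cal = calibrate_mu(
        eff.kinetic_model(mu=0.0),
        target_density,
        tolerance=0.005,
        effective_length_bp=free_length,
        protocol=SimulationProtocol(
            n_replicas=2, t_end=400.0, burn_in=200.0, sample_interval=1.0,
            seed=1234,
        ),
    )
    return tuple(table), cal.mu


def calibrated_equilibrium(
    enzyme_rate: float = 0.0,
    barrier_height: float = 25.0,
    positioning_depth: float = 0.0,
    target_density: float = DEFAULT_TARGET_DENSITY,
) -> tuple[EffectiveModel, float]:
    """Effective model + calibrated chemical potential for a scenario."""
    import numpy as np

    table, mu = _cached_calibration(
        float(enzyme_rate), float(barrier_height), float(positioning_depth),
        float(target_density),
    )
    field = scenario_field(barrier_height, positioning_depth)
    pair = PairPotential(
        hard_core_bp=field.lattice.footprint_bp,
        effective_attraction=np.asarray(table),
    )
    return EffectiveModel(field=field, pair=pair, enzyme_rate=enzyme_rate), mu


def phase_point_ensemble(
    positioning_depth: float,
    enzyme_rate: float,
    seed: int = 0,
    n_replicas: int = 4,
    t_end: float = 1000.0,
    barrier_height: float = 25.0,
    target_density: float = DEFAULT_TARGET_DENSITY,
):
    """Equilibrium ensemble for one (depth, enzyme rate) phase-grid point."""
    eff, mu = calibrated_equilibrium(
        enzyme_rate, barrier_height, positioning_depth, target_density
    )
    protocol = SimulationProtocol(
        n_replicas=n_replicas, t_end=t_end, burn_in=min(400.0, t_end / 3),
        sample_interval=1.0, seed=seed,
    )
    return sample_equilibrium(eff, protocol, mu=mu)
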