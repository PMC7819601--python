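"""Stochastic kinetics of nucleosomes: diffusion, spacer enzymes, exchange.

The model couples three processes on the hard-rod lattice of `lattice`:

* thermal diffusion -- 1-bp hops at rate ``(D / dl^2) exp(-dU/2)``, which
  satisfies detailed balance with respect to the total energy;
* spacer-enzyme remodeling (ISW1/Chd1-like) -- an enzyme captures a pair of
  neighbouring nucleosomes whose dyad distance is at most
  ``enzyme_range_bp`` and moves one of them (chosen at random) toward the
  other by 1 bp at an energy-independent rate ``k``, breaking detailed
  balance;
* histone exchange -- whole-nucleosome absorption/desorption at rates
  ``r_on = r_const exp(-(dU+mu)/2)`` and ``r_off = r_const exp(+(dU+mu)/2)``
  where ``mu`` is a chemical potential controlling mean density.

`gillespie_step`/`enumerate_events` are a transparent pure-Python reference
used in tests; `run_simulation` drives the compiled kernel in `_engine` for
production ensembles.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field as dc_field
from typing import Iterable, Iterator, Sequence

import numpy as np

from ._engine import run_gillespie
from .lattice import (
    EnergyField,
    LatticeSpec,
    Move,
    NucleosomeConfiguration,
    PairPotential,
    apply_move,
    delta_energy,
)

__all__ = [
    "KineticModel",
    "SimulationProtocol",
    "EnsembleRecord",
    "Event",
    "diffusion_rate",
    "exchange_rates",
    "enumerate_events",
    "gillespie_step",
    "run_simulation",
    "random_initial_configuration",
    "calibrate_mu",
    "CalibrationResult",
    "CalibrationError",
]


def diffusion_rate(dU: float, D: float = 1.0, step_bp: float = 1.0) -> float:
    """Hop rate ``(D/step^2) exp(-dU/2)``; zero for blocked (infinite) moves."""
    if math.isinf(dU) and dU > 0:
        return 0.0
    return (D / step_bp**2) * math.exp(-dU / 2.0)


def exchange_rates(dU: float, mu: float, r_const: float) -> tuple[float, float]:
    """Absorption/desorption rate pair for an energy change ``dU``.

    ``r_on = r_const exp(-dV/2)``, ``r_off = r_const exp(+dV/2)`` with
    ``dV = dU + mu``, so that ``r_on / r_off = exp(-dV)`` exactly
    (detailed balance with respect to the grand potential).
    """
    if r_const < 0:
        raise ValueError("r_const must be >= 0")
    dV = dU + mu
    if math.isinf(dV):
        return (0.0, math.inf) if dV > 0 else (math.inf, 0.0)
    return r_const * math.exp(-dV / 2.0), r_const * math.exp(dV / 2.0)


@dataclass
class KineticModel:
    """All rate parameters plus the energy model.

    Units: ``D`` in bp^2/s, ``step_bp`` in bp, ``enzyme_rate`` and
    ``r_const`` in 1/s, ``mu`` in k_B T, ``enzyme_range_bp`` a dyad-to-dyad
    capture distance.
    """

    field: EnergyField
    pair: PairPotential = dc_field(default_factory=PairPotential)
    D: float = 1.0
    step_bp: float = 1.0
    enzyme_rate: float = 0.0
    enzyme_range_bp: int = 332
    r_const: float = 0.0
    mu: float = 0.0

    def __post_init__(self) -> None:
        if min(self.D, self.enzyme_rate, self.r_const) < 0:
            raise ValueError("all rates must be >= 0")
        if self.enzyme_range_bp < self.field.lattice.footprint_bp:
            raise ValueError("enzyme_range_bp must be >= footprint_bp")

    @property
    def lattice(self) -> LatticeSpec:
        return self.field.lattice

    def fingerprint(self) -> str:
        payload = {
            "D": self.D,
            "step_bp": self.step_bp,
            "enzyme_rate": self.enzyme_rate,
            "enzyme_range_bp": self.enzyme_range_bp,
            "r_const": self.r_const,
            "mu": self.mu,
            "lattice": (self.lattice.length_bp, self.lattice.tss_index,
                        self.lattice.footprint_bp),
            "field_sha": hashlib.sha1(
                np.ascontiguousarray(self.field.dyad_energies()).tobytes()
            ).hexdigest(),
            "u_eff_sha": hashlib.sha1(
                b"" if self.pair.effective_attraction is None
                else np.ascontiguousarray(self.pair.effective_attraction).tobytes()
            ).hexdigest(),
        }
        return hashlib.sha1(json.dumps(payload, sort_keys=True).encode()).hexdigest()


@dataclass
class SimulationProtocol:
    """Replica count, time grid and seeding of an ensemble run."""

    n_replicas: int = 1
    t_end: float = 5000.0
    burn_in: float = 2500.0
    sample_interval: float = 2.0
    initial_n_nucleosomes: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not (self.t_end > self.burn_in >= 0):
            raise ValueError("need t_end > burn_in >= 0")
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be > 0")
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")

    def replica_seeds(self) -> np.ndarray:
        """Child seeds: one uint32 per replica from a master SeedSequence."""
        return np.random.SeedSequence(self.seed).generate_state(self.n_replicas)

    def fingerprint(self) -> str:
        return (
            f"replicas:{self.n_replicas}|t_end:{self.t_end}|burn_in:{self.burn_in}|"
            f"dt:{self.sample_interval}|n0:{self.initial_n_nucleosomes}|"
            f"seed:{self.seed}|rng:numba-mt19937/seedsequence-uint32"
        )


@dataclass
class EnsembleRecord:
    """Time-stamped sampled configurations across replicas."""

    replica_ids: np.ndarray
    times: np.ndarray
    dyads: list[np.ndarray]
    lattice: LatticeSpec
    model_fingerprint: str = ""
    protocol_fingerprint: str = ""

    def __post_init__(self) -> None:
        foot = self.lattice.footprint_bp
        L = self.lattice.length_bp
        for d in self.dyads:
            if d.size >= 2:
                gaps = np.diff(d, append=d[0] + L)
                if gaps.min() < foot:
                    raise AssertionError("sampled configuration violates exclusion")

    @property
    def n_samples(self) -> int:
        return len(self.dyads)

    def counts(self) -> np.ndarray:
        return np.array([d.size for d in self.dyads], dtype=np.int64)

    def configurations(self) -> Iterator[np.ndarray]:
        return iter(self.dyads)

    def mean_density(self) -> float:
        """Mean occupied fraction: <n> * footprint / length."""
        return float(self.counts().mean()) * self.lattice.footprint_bp / self.lattice.length_bp

    @classmethod
    def concat(cls, records: Sequence["EnsembleRecord"]) -> "EnsembleRecord":
        first = records[0]
        return cls(
            replica_ids=np.concatenate([r.replica_ids for r in records]),
            times=np.concatenate([r.times for r in records]),
            dyads=[d for r in records for d in r.dyads],
            lattice=first.lattice,
            model_fingerprint=first.model_fingerprint,
            protocol_fingerprint=first.protocol_fingerprint,
        )


@dataclass(frozen=True)
class Event:
    """A reaction channel: a configuration move plus its propensity."""

    kind: str  # "hop" | "insert" | "remove" | "enzyme"
    rate: float
    index: int | None = None
    step: int | None = None
    dyad: int | None = None
    pair_index: int | None = None


def enumerate_events(config: NucleosomeConfiguration, model: KineticModel) -> list[Event]:
    """All reaction channels of the current configuration with their rates.

    Channels: per-nucleosome 1-bp hops at the diffusion rate; one
    spacer-enzyme channel per circularly consecutive pair with dyad gap in
    ``(footprint, enzyme_range_bp]`` at rate ``k`` (the mover is chosen
    uniformly at firing time); per-nucleosome desorption and per-free-dyad
    absorption at the exchange rates.
    """
    events: list[Event] = []
    lat = config.lattice
    L = lat.length_bp
    foot = lat.footprint_bp
    d = config.dyads
    n = config.n
    fld, pair = model.field, model.pair

    if model.D > 0:
        for i in range(n):
            for step in (-1, +1):
                dU = delta_energy(config, Move("hop", index=i, step=step), fld, pair)
                r = diffusion_rate(dU, model.D, model.step_bp)
                if r > 0:
                    events.append(Event("hop", r, index=i, step=step))
    if model.enzyme_rate > 0 and n >= 2:
        gaps = config.gaps()
        for i in range(n):
            if foot < gaps[i] <= model.enzyme_range_bp:
                events.append(Event("enzyme", model.enzyme_rate, pair_index=i))
    if model.r_const > 0:
        for i in range(n):
            dU = delta_energy(config, Move("remove", index=i), fld, pair)
            _, r_off = exchange_rates(-dU, model.mu, model.r_const)
            # r_off uses the insertion-direction energy change of this rod
            events.append(Event("remove", r_off, index=i))
        for x in _free_dyad_sites(config):
            dU = delta_energy(config, Move("insert", dyad=x), fld, pair)
            if math.isinf(dU):
                continue
            r_on, _ = exchange_rates(dU, model.mu, model.r_const)
            events.append(Event("insert", r_on, dyad=x))
    return events


def _free_dyad_sites(config: NucleosomeConfiguration) -> Iterable[int]:
    """Dyad positions whose full footprint is unoccupied."""
    L = config.lattice.length_bp
    foot = config.lattice.footprint_bp
    d = config.dyads
    n = config.n
    if n == 0:
        yield from range(L)
        return
    gaps = config.gaps()
    for i in range(n):
        g = int(gaps[i])
        if g >= 2 * foot:
            for o in range(foot, g - foot + 1):
                yield int((d[i] + o) % L)


def _enzyme_movers(config: NucleosomeConfiguration, pair_index: int) -> list[Move]:
    """Feasible 1-bp inward moves of the pair's members."""
    n = config.n
    i, j = pair_index, (pair_index + 1) % n
    moves = []
    for idx, step in ((i, +1), (j, -1)):
        try:
            after = apply_move(config, Move("hop", index=idx, step=step))
            after.validate()
            moves.append(Move("hop", index=idx, step=step))
        except ValueError:
            continue
    return moves


def gillespie_step(
    config: NucleosomeConfiguration,
    model: KineticModel,
    rng: np.random.Generator,
) -> tuple[NucleosomeConfiguration, float]:
    """One exact SSA step: exponential waiting time, rate-proportional event.

    Raises ``RuntimeError`` when the total rate is zero (absorbing state);
    callers should then advance their clock to the horizon.
    """
    events = enumerate_events(config, model)
    rates = np.array([e.rate for e in events])
    total = rates.sum()
    if total <= 0:
        raise RuntimeError("absorbing state: total event rate is zero")
    dt = rng.exponential(1.0 / total)
    e = events[rng.choice(len(events), p=rates / total)]
    if e.kind == "enzyme":
        movers = _enzyme_movers(config, e.pair_index)
        move = movers[rng.integers(len(movers))]
    elif e.kind == "hop":
        move = Move("hop", index=e.index, step=e.step)
    elif e.kind == "insert":
        move = Move("insert", dyad=e.dyad)
    else:
        move = Move("remove", index=e.index)
    return apply_move(config, move), dt


def crystalline_configuration(
    n: int,
    lattice: LatticeSpec,
    start_offset: int = 74,
) -> NucleosomeConfiguration:
    """``n`` rods packed at contact (gap = footprint) in a single cluster.

    The cluster starts ``start_offset`` bp downstream of the TSS, leaving
    the remaining slack as one void that ends at the promoter.  Useful as
    a calibration initial state: under attractive effective potentials it
    is close to the typical configuration, and it leaves one large void so
    absorption/desorption dynamics are never jammed at the start.
    """
    L, foot = lattice.length_bp, lattice.footprint_bp
    if n < 0 or n > lattice.capacity:
        raise ValueError(
            f"cannot place {n} nucleosomes on a lattice of capacity {lattice.capacity}"
        )
    dyads = (lattice.tss_index + start_offset + foot * np.arange(n)) % L
    return NucleosomeConfiguration(np.sort(dyads).astype(np.int64), lattice)


def random_initial_configuration(
    n: int,
    lattice: LatticeSpec,
    rng: np.random.Generator,
) -> NucleosomeConfiguration:
    """Uniform random non-overlapping placement of ``n`` rods.

    Draws a uniform composition of the free slack into the ``n`` circular
    gaps (stars and bars) and a uniform rotation, which together make every
    feasible configuration equally likely.
    """
    L, foot = lattice.length_bp, lattice.footprint_bp
    if n < 0 or n > lattice.capacity:
        raise ValueError(
            f"cannot place {n} nucleosomes on a lattice of capacity {lattice.capacity}"
        )
    if n == 0:
        return NucleosomeConfiguration(np.empty(0, dtype=np.int64), lattice)
    slack = L - n * foot
    if n == 1:
        return NucleosomeConfiguration(
            np.array([rng.integers(L)], dtype=np.int64), lattice
        )
    bars = np.sort(rng.choice(slack + n - 1, size=n - 1, replace=False))
    parts = np.diff(np.concatenate([[-1], bars, [slack + n - 1]])) - 1
    gaps = foot + parts
    x0 = rng.integers(L)
    dyads = np.sort((x0 + np.concatenate([[0], np.cumsum(gaps[:-1])])) % L)
    return NucleosomeConfiguration(dyads.astype(np.int64), lattice)


def _dense_attraction(model: KineticModel) -> np.ndarray:
    L = model.lattice.length_bp
    u = np.zeros(L + 2)
    att = model.pair.effective_attraction
    if att is not None and att.size:
        hc = model.pair.hard_core_bp
        k = min(att.size, L + 2 - hc)
        u[hc : hc + k] = att[:k]
    return u


def run_simulation(
    model: KineticModel,
    protocol: SimulationProtocol,
    initial_configuration: NucleosomeConfiguration | None = None,
) -> EnsembleRecord:
    """Independent-replica Gillespie ensemble (compiled kernel).

    Bit-for-bit reproducible for a given protocol seed: replica seeds are
    derived from the master seed by a SeedSequence counter and each replica
    runs single-threaded Mersenne-Twister draws.  Replicas start from
    independent uniform random placements unless ``initial_configuration``
    is given (then every replica starts there).
    """
    lat = model.lattice
    n0 = protocol.initial_n_nucleosomes
    if n0 is None:
        n0 = min(lat.capacity, int(0.8 * lat.capacity) + 1)
    if n0 > lat.capacity:
        raise ValueError(
            f"initial_n_nucleosomes={n0} exceeds lattice capacity {lat.capacity}"
        )
    E1 = model.field.dyad_energies()
    u_att = _dense_attraction(model)
    seeds = protocol.replica_seeds()
    init_rng = np.random.default_rng(np.random.SeedSequence(protocol.seed).generate_state(1, dtype=np.uint64) + 1)

    rep_ids, times, dyads = [], [], []
    for rep in range(protocol.n_replicas):
        if initial_configuration is not None:
            cfg0 = initial_configuration
        else:
            cfg0 = random_initial_configuration(n0, lat, init_rng)
        counts, samples, _ = run_gillespie(
            cfg0.dyads.astype(np.int64),
            lat.length_bp,
            lat.footprint_bp,
            E1,
            u_att,
            float(model.D) / float(model.step_bp) ** 2,
            float(model.enzyme_rate),
            int(model.enzyme_range_bp),
            float(model.r_const),
            float(model.mu),
            float(protocol.t_end),
            float(protocol.burn_in),
            float(protocol.sample_interval),
            int(seeds[rep]),
        )
        for s in range(counts.size):
            rep_ids.append(rep)
            times.append(protocol.burn_in + s * protocol.sample_interval)
            dyads.append(samples[s, : counts[s]].astype(np.int64))
    return EnsembleRecord(
        replica_ids=np.asarray(rep_ids, dtype=np.int64),
        times=np.asarray(times, dtype=np.float64),
        dyads=dyads,
        lattice=lat,
        model_fingerprint=model.fingerprint(),
        protocol_fingerprint=protocol.fingerprint(),
    )


class CalibrationError(RuntimeError):
    """Chemical-potential calibration failed; carries the iteration trace."""

    def __init__(self, message: str, trace: list[tuple[float, float]]):
        super().__init__(f"{message}; trace={trace}")
        self.trace = trace


@dataclass
class CalibrationResult:
    """Outcome of a chemical-potential calibration."""

    mu: float
    density: float
    target_density: float
    trace: list[tuple[float, float]]

    def __float__(self) -> float:
        return self.mu


def calibrate_mu(
    model: KineticModel,
    target_density: float,
    tolerance: float = 0.01,
    protocol: SimulationProtocol | None = None,
    effective_length_bp: int | None = None,
    max_iter: int = 40,
) -> CalibrationResult:
    """Find mu so the steady-state mean occupied fraction hits a target.

    Density is ``<n> * footprint / effective_length_bp`` (the full lattice
    length by default; pass the barrier-free length to measure density over
    accessible DNA only).  Stochastic bisection on mu: the mean bound count
    is strictly decreasing in mu, so a bracket is expanded if necessary and
    then halved; each probe is a short absorption/desorption ensemble.
    """
    if not (0 < target_density < 1):
        raise ValueError("target_density must be in (0, 1)")
    if model.r_const <= 0:
        raise ValueError("calibration needs r_const > 0 (density cannot change)")
    lat = model.lattice
    L_eff = effective_length_bp if effective_length_bp is not None else lat.length_bp
    n_target = int(round(target_density * L_eff / lat.footprint_bp))
    protocol = protocol or SimulationProtocol(
        n_replicas=2, t_end=120.0, burn_in=60.0, sample_interval=0.5, seed=1234,
    )
    # Probes start from a packed cluster with one large void: even when the
    # dynamics jam at a badly wrong mu (no insertable gap, negligible
    # desorption), the void first fills, so a frozen probe still reports a
    # density on the correct side of any sub-saturation target.
    init = crystalline_configuration(min(n_target, lat.capacity), lat)
    trace: list[tuple[float, float]] = []

    def density_at(mu: float) -> float:
        probe = KineticModel(
            field=model.field, pair=model.pair, D=model.D, step_bp=model.step_bp,
            enzyme_rate=model.enzyme_rate, enzyme_range_bp=model.enzyme_range_bp,
            r_const=model.r_const, mu=mu,
        )
        rec = run_simulation(probe, protocol, initial_configuration=init)
        dens = float(rec.counts().mean()) * lat.footprint_bp / L_eff
        trace.append((mu, dens))
        return dens

    center = -float(np.mean(model.field.dyad_energies()))
    att = model.pair.effective_attraction
    if att is not None and att.size:
        center -= 2.0 * float(np.min(att))  # attraction deepens binding
    lo, hi = center - 15.0, center + 15.0
    d_lo = density_at(lo)
    d_hi = density_at(hi)
    it = 2
    while d_lo < target_density and it < max_iter:
        lo -= 15.0
        d_lo = density_at(lo)
        it += 1
    while d_hi > target_density and it < max_iter:
        hi += 15.0
        d_hi = density_at(hi)
        it += 1
    if d_lo < target_density or d_hi > target_density:
        raise CalibrationError(
            f"could not bracket target density {target_density}", trace
        )
    mu, dens = lo, d_lo
    while it < max_iter:
        if hi - lo < 1e-4:
            # the isotherm jumps across the target (e.g. condensation on a
            # small ring with deep attraction): no mu attains it stably
            raise CalibrationError(
                f"density jumps discontinuously across target "
                f"{target_density} near mu={mu:.4f}", trace
            )
        mu = 0.5 * (lo + hi)
        dens = density_at(mu)
        it += 1
        if abs(dens - target_density) <= tolerance:
            return CalibrationResult(mu=mu, density=dens,
                                     target_density=target_density, trace=trace)
        if dens > target_density:
            lo = mu
        else:
            hi = mu
    raise CalibrationError(
        f"no convergence to density {target_density} +/- {tolerance} "
        f"after {max_iter} probes", trace
    )
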