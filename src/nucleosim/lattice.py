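"""One-dimensional lattice model of nucleosomes as hard rods.

The genome is a periodic lattice of base pairs.  A nucleosome is a hard rod
of 147 bp whose coordinate is its dyad (the central base pair); two dyads
closer than the footprint overlap and are forbidden.  Each base pair carries
a binding energy ``V_s`` (k_B T); in addition two dyad-evaluated potentials
act on the particle coordinate itself: a triangular *promoter barrier*
upstream of the transcription start site (TSS), which penalises nucleosome
formation over the promoter, and a flat *positioning well* just downstream
of the TSS, which mimics +1-positioning remodelers (INO80-like).

All energies are in units of k_B T (beta = 1).  Coordinates are 0-based
lattice indices; the footprint of a dyad at ``x`` occupies
``[x - 73, x + 73]`` with periodic wrap-around.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

__all__ = [
    "LatticeSpec",
    "NucleosomeConfiguration",
    "EnergyField",
    "PairPotential",
    "Move",
    "make_barrier",
    "make_positioning",
    "nucleosome_energy",
    "total_energy",
    "delta_energy",
]

FOOTPRINT_BP = 147
#: Uniform per-footprint binding free energy (k_B T) of a nucleosome.
DEFAULT_BINDING_ENERGY = -42.0


@dataclass(frozen=True)
class LatticeSpec:
    """Geometry of the periodic base-pair lattice.

    Parameters
    ----------
    length_bp
        Number of lattice sites (base pairs); default 14700.
    tss_index
        Lattice coordinate of the transcription start site.  Profile
        offsets are reported relative to this anchor.
    footprint_bp
        Length of the nucleosome footprint (odd, default 147).
    periodic
        Periodic boundary conditions (the only supported mode; kept as a
        field so configurations carry their geometry explicitly).
    """

    length_bp: int = 14700
    tss_index: int = 7350
    footprint_bp: int = FOOTPRINT_BP
    periodic: bool = True

    def __post_init__(self) -> None:
        if self.length_bp < self.footprint_bp:
            raise ValueError(
                f"length_bp={self.length_bp} smaller than footprint_bp={self.footprint_bp}"
            )
        if not (0 <= self.tss_index < self.length_bp):
            raise ValueError(f"tss_index={self.tss_index} outside [0, {self.length_bp})")
        if self.footprint_bp <= 0 or self.footprint_bp % 2 == 0:
            raise ValueError("footprint_bp must be a positive odd integer")
        if not self.periodic:
            raise ValueError("only periodic lattices are supported")

    @property
    def half_footprint(self) -> int:
        return self.footprint_bp // 2

    @property
    def capacity(self) -> int:
        """Maximum number of non-overlapping nucleosomes."""
        return self.length_bp // self.footprint_bp

    def wrap(self, x: int | np.ndarray) -> int | np.ndarray:
        return x % self.length_bp

    def offset_to_index(self, offset_bp: int) -> int:
        """Lattice index of a position given in bp relative to the TSS."""
        return (self.tss_index + offset_bp) % self.length_bp


def circular_gaps(dyads: np.ndarray, length_bp: int) -> np.ndarray:
    """Dyad-to-dyad distances between circularly consecutive nucleosomes.

    For ``n`` sorted dyads returns ``n`` gaps (the last wraps around the
    origin); their sum is ``length_bp``.  A single nucleosome has one gap of
    the full lattice length; an empty configuration has none.
    """
    dyads = np.asarray(dyads, dtype=np.int64)
    if dyads.size == 0:
        return np.empty(0, dtype=np.int64)
    return np.diff(dyads, append=dyads[0] + length_bp)


@dataclass
class NucleosomeConfiguration:
    """Sorted dyad positions of bound nucleosomes on a periodic lattice."""

    dyads: np.ndarray
    lattice: LatticeSpec = field(default_factory=LatticeSpec)

    def __post_init__(self) -> None:
        self.dyads = np.asarray(self.dyads, dtype=np.int64)
        self.validate()

    def validate(self) -> None:
        d = self.dyads
        L = self.lattice.length_bp
        if d.size and (d.min() < 0 or d.max() >= L):
            raise ValueError("dyads outside the lattice")
        if np.any(np.diff(d) <= 0):
            raise ValueError("dyads must be strictly increasing")
        gaps = circular_gaps(d, L)
        if d.size >= 2 and gaps.min() < self.lattice.footprint_bp:
            raise ValueError(
                f"exclusion violated: minimum circular gap {gaps.min()} < "
                f"footprint {self.lattice.footprint_bp}"
            )

    @property
    def n(self) -> int:
        return int(self.dyads.size)

    def gaps(self) -> np.ndarray:
        return circular_gaps(self.dyads, self.lattice.length_bp)

    def copy(self) -> "NucleosomeConfiguration":
        return NucleosomeConfiguration(self.dyads.copy(), self.lattice)


@dataclass
class EnergyField:
    """Binding-energy landscape: per-bp site energies plus dyad potentials.

    ``site_energy`` is the per-base-pair contribution ``V_s``; a nucleosome
    at dyad ``x`` pays the sum of ``site_energy`` over its 147-bp footprint.
    ``barrier`` (>= 0) and ``positioning`` (<= 0) are evaluated at the dyad
    coordinate only.
    """

    site_energy: np.ndarray
    barrier: np.ndarray | None = None
    positioning: np.ndarray | None = None
    lattice: LatticeSpec = field(default_factory=LatticeSpec)

    def __post_init__(self) -> None:
        L = self.lattice.length_bp
        self.site_energy = np.asarray(self.site_energy, dtype=np.float64)
        if self.site_energy.size == L and self.site_energy.ndim == 1:
            pass
        else:
            raise ValueError(f"site_energy must have exactly {L} entries")
        if self.barrier is None:
            self.barrier = np.zeros(L)
        if self.positioning is None:
            self.positioning = np.zeros(L)
        self.barrier = np.asarray(self.barrier, dtype=np.float64)
        self.positioning = np.asarray(self.positioning, dtype=np.float64)
        if self.barrier.size != L or self.positioning.size != L:
            raise ValueError("barrier/positioning must match the lattice length")
        if np.any(self.barrier < 0):
            raise ValueError("barrier potential must be >= 0 everywhere")
        if np.any(self.positioning > 0):
            raise ValueError("positioning potential must be <= 0 everywhere")

    @classmethod
    def uniform(
        cls,
        lattice: LatticeSpec | None = None,
        binding_energy: float = DEFAULT_BINDING_ENERGY,
        barrier: np.ndarray | None = None,
        positioning: np.ndarray | None = None,
    ) -> "EnergyField":
        """Uniform field whose 147-bp footprint sum equals ``binding_energy``."""
        lattice = lattice or LatticeSpec()
        per_bp = binding_energy / lattice.footprint_bp
        return cls(
            site_energy=np.full(lattice.length_bp, per_bp),
            barrier=barrier,
            positioning=positioning,
            lattice=lattice,
        )

    def dyad_energies(self) -> np.ndarray:
        """Total single-nucleosome energy at every dyad position.

        Footprint sum of ``site_energy`` (periodic) plus the dyad-evaluated
        barrier and positioning terms.  This is the quantity the simulation
        kernels consume.
        """
        L = self.lattice.length_bp
        w = self.lattice.footprint_bp
        h = self.lattice.half_footprint
        doubled = np.concatenate([self.site_energy, self.site_energy])
        cum = np.concatenate([[0.0], np.cumsum(doubled)])
        start = (np.arange(L) - h) % L
        footprint_sum = cum[start + w] - cum[start]
        return footprint_sum + self.barrier + self.positioning


@dataclass
class PairPotential:
    """Nearest-neighbour interaction between consecutive nucleosomes.

    Hard-core exclusion below ``hard_core_bp`` plus an optional tabulated
    effective attraction ``u_eff(gap)`` for gaps at and beyond the hard
    core (used by the equilibrium sampler to fold in spacer-enzyme
    effects).  ``effective_attraction[i]`` is the energy at gap
    ``hard_core_bp + i``; beyond the table the interaction is zero.
    """

    hard_core_bp: int = FOOTPRINT_BP
    effective_attraction: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.effective_attraction is not None:
            self.effective_attraction = np.asarray(
                self.effective_attraction, dtype=np.float64
            )

    def energy(self, gap: int | np.ndarray) -> float | np.ndarray:
        """Pair energy u(gap) in k_B T; +inf below the hard core."""
        gap_arr = np.asarray(gap)
        out = np.where(gap_arr < self.hard_core_bp, np.inf, 0.0)
        if self.effective_attraction is not None and self.effective_attraction.size:
            idx = gap_arr - self.hard_core_bp
            in_table = (idx >= 0) & (idx < self.effective_attraction.size)
            out = np.where(
                in_table,
                self.effective_attraction[np.clip(idx, 0, self.effective_attraction.size - 1)],
                out,
            )
        if np.isscalar(gap):
            return float(out)
        return out

    def table(self, max_gap: int) -> np.ndarray:
        """Dense table u(gap) for gap = 0..max_gap (with +inf hard core)."""
        return np.asarray(self.energy(np.arange(max_gap + 1)), dtype=np.float64)


def make_barrier(
    lattice: LatticeSpec,
    center_offset: int = -150,
    half_width: int = 150,
    height: float = 25.0,
) -> np.ndarray:
    """Triangular promoter barrier, evaluated at the dyad.

    The barrier models competition from transcription factors, the
    pre-initiation complex and Pol II over the promoter: a symmetric
    triangle centred at ``tss + center_offset`` of the given height that
    falls linearly to zero at ``center +/- half_width``.  A finite peak
    leaves nucleosomes a finite probability of occupying the promoter.

    Returns a per-dyad array of length ``lattice.length_bp``.
    """
    if height < 0:
        raise ValueError(f"barrier height must be >= 0, got {height}")
    if half_width <= 0:
        raise ValueError(f"barrier half_width must be > 0, got {half_width}")
    L = lattice.length_bp
    center = lattice.offset_to_index(center_offset)
    x = np.arange(L)
    # signed circular distance to the center, in [-L/2, L/2)
    dist = np.abs((x - center + L // 2) % L - L // 2)
    out = height * np.clip(1.0 - dist / half_width, 0.0, None)
    return out


def make_positioning(
    lattice: LatticeSpec,
    start_offset: int = 0,
    end_offset: int = 30,
    depth: float = -2.0,
) -> np.ndarray:
    """Flat positioning well downstream of the TSS, evaluated at the dyad.

    Models +1-positioning remodelers as an attractive square well of the
    given (non-positive) depth on ``[tss + start_offset, tss + end_offset]``
    inclusive, zero elsewhere.
    """
    if depth > 0:
        raise ValueError(f"positioning depth must be <= 0, got {depth}")
    if start_offset >= end_offset:
        raise ValueError("start_offset must be < end_offset")
    L = lattice.length_bp
    out = np.zeros(L)
    idx = np.arange(start_offset, end_offset + 1)
    out[(lattice.tss_index + idx) % L] = depth
    return out


def nucleosome_energy(dyad: int, field: EnergyField) -> float:
    """Binding energy of a single nucleosome at ``dyad`` (k_B T).

    Sum of the per-bp site energies over the 147-bp footprint (periodic
    wrap) plus the dyad-evaluated barrier and positioning potentials.
    """
    lat = field.lattice
    h = lat.half_footprint
    idx = (dyad + np.arange(-h, h + 1)) % lat.length_bp
    return float(
        field.site_energy[idx].sum() + field.barrier[dyad] + field.positioning[dyad]
    )


def total_energy(
    config: NucleosomeConfiguration,
    field: EnergyField,
    pair: PairPotential | None = None,
) -> float:
    """Total energy: all single-nucleosome terms plus circular pair terms."""
    pair = pair or PairPotential(hard_core_bp=config.lattice.footprint_bp)
    config.validate()
    e = sum(nucleosome_energy(int(d), field) for d in config.dyads)
    if config.n >= 2:
        e += float(np.sum(pair.energy(config.gaps())))
    return float(e)


@dataclass(frozen=True)
class Move:
    """An elementary configuration change.

    ``kind`` is ``"hop"`` (nucleosome ``index`` shifts by ``step`` = +/-1 bp),
    ``"insert"`` (new nucleosome at ``dyad``) or ``"remove"`` (nucleosome
    ``index`` leaves the lattice).
    """

    kind: Literal["hop", "insert", "remove"]
    index: int | None = None
    step: int | None = None
    dyad: int | None = None


def apply_move(config: NucleosomeConfiguration, move: Move) -> NucleosomeConfiguration:
    """Configuration after ``move`` (raises if the result is invalid)."""
    L = config.lattice.length_bp
    d = config.dyads.copy()
    if move.kind == "hop":
        d[move.index] = (d[move.index] + move.step) % L
        d = np.sort(d)
    elif move.kind == "insert":
        d = np.sort(np.append(d, move.dyad % L))
    elif move.kind == "remove":
        d = np.delete(d, move.index)
    else:  # pragma: no cover - guarded by Move's type
        raise ValueError(f"unknown move kind {move.kind!r}")
    return NucleosomeConfiguration(d, config.lattice)


def delta_energy(
    config: NucleosomeConfiguration,
    move: Move,
    field: EnergyField,
    pair: PairPotential | None = None,
) -> float:
    """Energy change of ``move``, computed from the affected terms only.

    Equals ``total_energy(after) - total_energy(before)`` exactly; returns
    ``+inf`` iff the move violates hard-core exclusion.
    """
    pair = pair or PairPotential(hard_core_bp=config.lattice.footprint_bp)
    L = config.lattice.length_bp
    d = config.dyads
    n = config.n

    def u(gap: int) -> float:
        return float(pair.energy(int(gap)))

    if move.kind == "hop":
        i = move.index
        x = int(d[i])
        x_new = (x + move.step) % L
        de = nucleosome_energy(x_new, field) - nucleosome_energy(x, field)
        if n >= 2:
            left = int(d[(i - 1) % n])
            right = int(d[(i + 1) % n])
            gl = (x - left) % L
            gr = (right - x) % L
            if n == 2:
                gr = L - gl  # both circular gaps involve the same neighbour
            de += u(gl + move.step) - u(gl) + u(gr - move.step) - u(gr)
        return de

    if move.kind == "insert":
        x = move.dyad % L
        de = nucleosome_energy(x, field)
        if n == 0:
            return de
        j = int(np.searchsorted(d, x))
        left = int(d[(j - 1) % n])
        right = int(d[j % n])
        gl = (x - left) % L
        gr = (right - x) % L
        if n == 1:
            gr = L - gl
        if gl < pair.hard_core_bp or gr < pair.hard_core_bp:
            return math.inf
        de += u(gl) + u(gr)
        if n >= 2:
            de -= u(gl + gr)
        return de

    if move.kind == "remove":
        i = move.index
        x = int(d[i])
        de = -nucleosome_energy(x, field)
        if n >= 2:
            left = int(d[(i - 1) % n])
            right = int(d[(i + 1) % n])
            gl = (x - left) % L
            gr = (right - x) % L
            if n == 2:
                gr = L - gl
            de -= u(gl) + u(gr)
            if n >= 3:
                de += u(gl + gr)
        return de

    raise ValueError(f"unknown move kind {move.kind!r}")  # pragma: no cover
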