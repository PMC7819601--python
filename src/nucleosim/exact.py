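"""Exact reference results for small hard-rod systems.

Independent of the stochastic machinery: everything here is computed by
direct enumeration or by convolution over gap compositions, and serves as
the ground truth the samplers are tested against.

A configuration of ``n`` rods on a periodic lattice of ``L`` sites is
equivalent to a first dyad position plus a composition of ``L`` into ``n``
circular gaps, each at least the hard core.  Boltzmann weights factorise
into per-dyad field terms and nearest-neighbour gap terms, which makes the
fixed-``n`` partition sums tractable either by brute force (n <= 3 with a
field) or by repeated convolution of the gap weight (uniform field, any n).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

__all__ = [
    "enumerate_configurations",
    "exact_fixed_n_marginals",
    "grand_canonical_density",
    "ring_gap_distribution",
    "two_state_occupancy",
]


def _pair_table(u_table: np.ndarray | None, hard_core: int, max_gap: int) -> np.ndarray:
    """Dense u(gap) over 0..max_gap with +inf below the hard core."""
    u = np.zeros(max_gap + 1)
    u[:hard_core] = np.inf
    if u_table is not None:
        u_table = np.asarray(u_table, dtype=np.float64)
        k = min(u_table.size, max_gap + 1 - hard_core)
        u[hard_core : hard_core + k] = u_table[:k]
    return u


def enumerate_configurations(L: int, n: int, hard_core: int = 147):
    """Yield every sorted n-tuple of dyads with all circular gaps >= hard_core.

    Brute force; intended for n <= 3 on sub-kilobase lattices.
    """
    if n == 0:
        yield ()
        return
    if n == 1:
        for x in range(L):
            yield (x,)
        return
    # first dyad anywhere; remaining as a gap composition
    for x0 in range(L):
        for gaps in _gap_compositions(L, n, hard_core):
            dyads = np.cumsum((x0,) + gaps[:-1])
            if dyads[-1] < L and dyads[0] == x0 and np.all(np.diff(dyads) > 0):
                # emit only canonically-rooted tuples (smallest dyad first)
                if x0 == min(dyads % L):
                    yield tuple(int(d) for d in dyads)


def _gap_compositions(L: int, n: int, hard_core: int):
    """All n-tuples of gaps >= hard_core summing to L."""
    slack = L - n * hard_core
    if slack < 0:
        return
    for cuts in itertools.combinations_with_replacement(range(slack + 1), n - 1):
        parts = np.diff((0,) + cuts + (slack,))
        # combinations_with_replacement enumerates sorted cut positions which
        # is exactly the set of weak compositions of slack into n parts
        yield tuple(int(hard_core + p) for p in parts)


def _config_weight(
    dyads: tuple[int, ...],
    L: int,
    dyad_energy: np.ndarray,
    u: np.ndarray,
) -> float:
    e = float(sum(dyad_energy[d] for d in dyads))
    n = len(dyads)
    if n >= 2:
        d = np.asarray(dyads)
        gaps = np.diff(d, append=d[0] + L)
        e += float(np.sum(u[gaps]))
    return float(np.exp(-e))


def exact_fixed_n_marginals(
    L: int,
    n: int,
    dyad_energy: np.ndarray,
    hard_core: int = 147,
    u_table: np.ndarray | None = None,
):
    """Exact Boltzmann marginals for n rods on a ring with a dyad field.

    Returns ``(dyad_marginal, gap_marginal, log_Z)`` where ``dyad_marginal``
    is the probability that any given site holds a dyad (normalised to sum
    to n) and ``gap_marginal`` is the distribution of a circular
    nearest-neighbour gap (length L+1, indexed by gap).

    Brute-force enumeration; use only for n <= 3 and small L.
    """
    dyad_energy = np.asarray(dyad_energy, dtype=np.float64)
    u = _pair_table(u_table, hard_core, L)
    dyad_marg = np.zeros(L)
    gap_marg = np.zeros(L + 1)
    Z = 0.0
    for cfg in enumerate_configurations(L, n, hard_core):
        w = _config_weight(cfg, L, dyad_energy, u)
        Z += w
        for d in cfg:
            dyad_marg[d] += w
        if n >= 2:
            d = np.asarray(cfg)
            gaps = np.diff(d, append=d[0] + L)
            for g in gaps:
                gap_marg[g] += w / n
    if Z <= 0:
        raise ValueError("no feasible configurations")
    dyad_marg /= Z
    if gap_marg.sum() > 0:
        gap_marg /= gap_marg.sum()
    return dyad_marg, gap_marg, float(np.log(Z))


def grand_canonical_density(
    L: int,
    dyad_energy: np.ndarray,
    mu: float,
    max_n: int = 3,
    hard_core: int = 147,
    u_table: np.ndarray | None = None,
) -> float:
    """Exact grand-canonical mean occupied fraction on a small ring.

    Sums Boltzmann weights ``exp(-(U + mu * n))`` over all configurations
    with ``n <= max_n`` and returns ``<n> * hard_core / L``.  ``max_n``
    must be at least the packing capacity for the result to be exact.
    """
    dyad_energy = np.asarray(dyad_energy, dtype=np.float64)
    u = _pair_table(u_table, hard_core, L)
    Z = 0.0
    N_acc = 0.0
    for n in range(0, max_n + 1):
        for cfg in enumerate_configurations(L, n, hard_core):
            w = _config_weight(cfg, L, dyad_energy, u) * np.exp(-mu * n)
            Z += w
            N_acc += n * w
    return float(N_acc / Z) * hard_core / L


def grand_canonical_marginals(
    L: int,
    dyad_energy: np.ndarray,
    mu: float,
    max_n: int = 3,
    hard_core: int = 147,
    u_table: np.ndarray | None = None,
):
    """Exact grand-canonical P(N) and dyad marginal on a small ring.

    Returns ``(p_n, dyad_marginal)`` with ``p_n[n]`` the probability of n
    bound rods and ``dyad_marginal[x]`` the mean dyad count at site x
    (sums to <n>).  Exact when ``max_n`` reaches the packing capacity.
    """
    dyad_energy = np.asarray(dyad_energy, dtype=np.float64)
    u = _pair_table(u_table, hard_core, L)
    z_n = np.zeros(max_n + 1)
    marg = np.zeros((max_n + 1, L))
    for n in range(0, max_n + 1):
        for cfg in enumerate_configurations(L, n, hard_core):
            w = _config_weight(cfg, L, dyad_energy, u) * np.exp(-mu * n)
            z_n[n] += w
            for d in cfg:
                marg[n, d] += w
    Z = z_n.sum()
    return z_n / Z, marg.sum(axis=0) / Z


def ring_gap_distribution(
    L: int,
    n: int,
    hard_core: int = 147,
    u_table: np.ndarray | None = None,
) -> np.ndarray:
    """Exact circular-gap distribution for n rods on a uniform ring.

    With a uniform field the configuration weight depends only on the gaps:
    ``P(g_1..g_n) ∝ prod w(g_i)`` with ``w(g) = exp(-u(g))`` on
    ``g >= hard_core`` and ``sum g_i = L``.  The single-gap marginal is
    ``P(g) ∝ w(g) * (w^{*(n-1)})(L - g)`` computed by repeated convolution.

    Returns an array of length L+1 indexed by gap, summing to 1.
    """
    if n < 2:
        raise ValueError("gap distribution requires n >= 2")
    u = _pair_table(u_table, hard_core, L)
    w = np.exp(-np.clip(u, None, 700.0))
    w[:hard_core] = 0.0
    # normalise to keep convolutions in range
    scale = w.max()
    if scale <= 0:
        raise ValueError("no feasible gap")
    w_n = w / scale
    conv = w_n.copy()
    for _ in range(n - 2):
        conv = np.convolve(conv, w_n)[: L + 1]
    # P(g) ∝ w(g) * conv(L - g)
    out = np.zeros(L + 1)
    g = np.arange(L + 1)
    rem = L - g
    valid = (rem >= 0) & (rem < conv.size)
    out[valid] = w_n[g[valid]] * conv[rem[valid]]
    total = out.sum()
    if total <= 0:
        raise ValueError(f"no feasible configuration of {n} rods on L={L}")
    return out / total


@dataclass(frozen=True)
class two_state_occupancy:
    """Closed-form stationary occupancy of a single binding site.

    For insertion at rate ``r_on = r e^{-dV/2}`` and removal at
    ``r_off = r e^{+dV/2}``, the stationary odds of being occupied are
    ``exp(-dV)``; ``probability`` is the occupied fraction.
    """

    dV: float

    @property
    def odds(self) -> float:
        return float(np.exp(-self.dV))

    @property
    def probability(self) -> float:
        return self.odds / (1.0 + self.odds)
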