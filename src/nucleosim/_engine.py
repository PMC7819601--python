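"""Compiled Gillespie core.

One kernel drives every protocol: thermal diffusion (rate ``D e^{-dU/2}``
per 1-bp hop), spacer-enzyme remodeling (energy-independent rate ``k`` per
eligible nucleosome pair, moving one member toward the other), and histone
exchange (absorption ``r_const e^{-(dU+mu)/2}`` per free dyad site,
desorption ``r_const e^{+(dU+mu)/2}`` per bound nucleosome).  Protocols
select a subset by zeroing the corresponding rate constants.

Rates are recomputed from the current configuration at every step; with at
most ~100 rods the full O(n + free sites) sweep is a few microseconds and
is trivially consistent with the energy model in `lattice` (tested against
it).  Positions are kept sorted; wrap-around hops rotate the array.

Not part of the public API.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["run_gillespie", "MAX_EXP_ARG"]

MAX_EXP_ARG = 700.0


@njit(cache=True)
def _insert_sorted(pos, n, d):
    j = n
    for i in range(n):
        if pos[i] > d:
            j = i
            break
    for i in range(n, j, -1):
        pos[i] = pos[i - 1]
    pos[j] = d
    return n + 1


@njit(cache=True)
def _remove_at(pos, n, i):
    for j in range(i, n - 1):
        pos[j] = pos[j + 1]
    return n - 1


@njit(cache=True)
def _hop(pos, n, i, step, L):
    """Move rod i by step (+/-1), keeping the array sorted under wrap."""
    x = pos[i] + step
    if x < 0:
        # only the smallest rod can wrap below 0
        for j in range(n - 1):
            pos[j] = pos[j + 1]
        pos[n - 1] = L - 1
    elif x >= L:
        for j in range(n - 1, 0, -1):
            pos[j] = pos[j - 1]
        pos[0] = 0
    else:
        pos[i] = x


@njit(cache=True)
def _step_rates_and_fire(
    pos, n, L, foot, E1, u_att, D, k_enz, enz_range, r_const, mu, target, fire
):
    """Total event rate; when ``fire`` also select/apply the event at ``target``.

    Returns (total_rate, new_n).  Event classes are scanned in a fixed
    order (hops, removals, enzyme pairs, insertions) in both passes.
    """
    acc = 0.0
    # --- hops and removals, per rod ---
    if n > 0 and (D > 0.0 or r_const > 0.0):
        for i in range(n):
            x = pos[i]
            if n >= 2:
                lx = pos[(i - 1) % n]
                rx = pos[(i + 1) % n]
                gl = (x - lx) % L
                gr = (rx - x) % L
                if n == 2:
                    gr = L - gl
            else:
                gl = L
                gr = L
            if D > 0.0:
                # hop left
                if gl > foot:
                    dU = E1[(x - 1) % L] - E1[x]
                    if n >= 2:
                        dU += u_att[gl - 1] - u_att[gl] + u_att[gr + 1] - u_att[gr]
                    r = D * np.exp(-min(dU, MAX_EXP_ARG) / 2.0)
                    acc += r
                    if fire and acc > target:
                        _hop(pos, n, i, -1, L)
                        return acc, n
                # hop right
                if gr > foot:
                    dU = E1[(x + 1) % L] - E1[x]
                    if n >= 2:
                        dU += u_att[gr - 1] - u_att[gr] + u_att[gl + 1] - u_att[gl]
                    r = D * np.exp(-min(dU, MAX_EXP_ARG) / 2.0)
                    acc += r
                    if fire and acc > target:
                        _hop(pos, n, i, +1, L)
                        return acc, n
            if r_const > 0.0:
                bind = E1[x]
                if n >= 2:
                    bind += u_att[gl] + u_att[gr] - u_att[gl + gr]
                arg = (bind + mu) / 2.0
                r = r_const * np.exp(min(arg, MAX_EXP_ARG))
                acc += r
                if fire and acc > target:
                    n = _remove_at(pos, n, i)
                    return acc, n
    # --- enzyme pair events ---
    if k_enz > 0.0 and n >= 2:
        for i in range(n):
            g = (pos[(i + 1) % n] - pos[i]) % L
            if i == n - 1 and n >= 2:
                g = (pos[0] - pos[i]) % L
            if g > foot and g <= enz_range:
                acc += k_enz
                if fire and acc > target:
                    # move one pair member toward the other, chosen 50/50
                    if np.random.random() < 0.5:
                        _hop(pos, n, i, +1, L)
                    else:
                        _hop(pos, n, (i + 1) % n, -1, L)
                    return acc, n
    # --- insertions, per gap ---
    if r_const > 0.0:
        if n == 0:
            for d in range(L):
                dU = E1[d]
                r = r_const * np.exp(min(-(dU + mu) / 2.0, MAX_EXP_ARG))
                acc += r
                if fire and acc > target:
                    n = _insert_sorted(pos, n, d)
                    return acc, n
        else:
            for i in range(n):
                g = (pos[(i + 1) % n] - pos[i]) % L
                if n == 1:
                    g = L
                if g < 2 * foot:
                    continue
                base = pos[i]
                for o in range(foot, g - foot + 1):
                    d = (base + o) % L
                    dU = E1[d] + u_att[o] + u_att[g - o] - u_att[g]
                    r = r_const * np.exp(min(-(dU + mu) / 2.0, MAX_EXP_ARG))
                    acc += r
                    if fire and acc > target:
                        n = _insert_sorted(pos, n, d)
                        return acc, n
    return acc, n


@njit(cache=True)
def run_gillespie(
    pos0,
    L,
    foot,
    E1,
    u_att,
    D,
    k_enz,
    enz_range,
    r_const,
    mu,
    t_end,
    burn_in,
    sample_dt,
    seed,
):
    """Simulate one trajectory, sampling configurations on a time grid.

    Returns (sample_counts, sample_positions, n_events) where
    ``sample_positions[s, :sample_counts[s]]`` are the sorted dyads at
    sample time ``burn_in + s * sample_dt``.
    """
    np.random.seed(seed)
    max_n = L // foot + 1
    n_samp = int(np.floor((t_end - burn_in) / sample_dt)) + 1
    counts = np.zeros(n_samp, dtype=np.int32)
    samples = np.full((n_samp, max_n), -1, dtype=np.int32)
    pos = np.zeros(max_n + 1, dtype=np.int64)
    n = pos0.size
    for i in range(n):
        pos[i] = pos0[i]

    t = 0.0
    next_s = 0
    n_events = 0
    while next_s < n_samp:
        total, _ = _step_rates_and_fire(
            pos, n, L, foot, E1, u_att, D, k_enz, enz_range, r_const, mu, -1.0, False
        )
        if total <= 0.0:
            # absorbing state: the configuration persists to t_end
            while next_s < n_samp:
                counts[next_s] = n
                for i in range(n):
                    samples[next_s, i] = np.int32(pos[i])
                next_s += 1
            break
        u = np.random.random()
        while u <= 0.0:
            u = np.random.random()
        t_next = t + (-np.log(u) / total)
        while next_s < n_samp and burn_in + next_s * sample_dt <= t_next:
            counts[next_s] = n
            for i in range(n):
                samples[next_s, i] = np.int32(pos[i])
            next_s += 1
        if next_s >= n_samp:
            break
        t = t_next
        target = np.random.random() * total
        _, n = _step_rates_and_fire(
            pos, n, L, foot, E1, u_att, D, k_enz, enz_range, r_const, mu, target, True
        )
        n_events += 1
    return counts, samples, n_events
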