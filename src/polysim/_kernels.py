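"""Compiled inner loop of the lattice polymerization simulator.

One call advances the strand arrays by a single fixed time step:
site-by-site bond formation, then strand-by-strand hydrolysis, then
strand-by-strand hopping to a Moore neighbour on the periodic lattice.
Strands are stored as parallel arrays ``lengths`` / ``sites`` with ``n``
active entries; capacity must be at least the total monomer count (the
strand count can never exceed it).  All randomness flows through the
caller's ``numpy.random.Generator`` so the draw order is reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# Moore neighbourhood displacements (8 neighbours)
_DX = np.array([-1, 0, 1, -1, 1, -1, 0, 1], dtype=np.int64)
_DY = np.array([-1, -1, -1, 0, 0, 1, 1, 1], dtype=np.int64)


@njit(cache=True)
def step_kernel(lengths, sites, n, n_sites, side, k_plus, k_minus, h, dt, rng):
    """Advance one time step in place; return (new_n, clamp_count).

    Event probabilities are ``k+ n(n-1) dt`` per site (one bond at most),
    ``k- (m-1) dt`` per strand (one break at most, fragments stay put and
    are not revisited this step), ``h dt`` per strand (hop always accepted).
    Probabilities exceeding 1 are clamped and counted.
    """
    clamp = 0

    if k_plus > 0.0 and n >= 2:
        counts = np.zeros(n_sites, dtype=np.int64)
        for i in range(n):
            counts[sites[i]] += 1
        offsets = np.zeros(n_sites + 1, dtype=np.int64)
        for s in range(n_sites):
            offsets[s + 1] = offsets[s] + counts[s]
        order = np.empty(n, dtype=np.int64)
        fill = offsets[:n_sites].copy()
        for i in range(n):
            s = sites[i]
            order[fill[s]] = i
            fill[s] += 1
        for s in range(n_sites):
            ns = counts[s]
            if ns >= 2:
                p = k_plus * ns * (ns - 1) * dt
                if p > 1.0:
                    p = 1.0
                    clamp += 1
                if rng.random() < p:
                    i = rng.integers(0, ns)
                    j = rng.integers(0, ns - 1)
                    if j >= i:
                        j += 1
                    gi = order[offsets[s] + i]
                    gj = order[offsets[s] + j]
                    lengths[gi] += lengths[gj]
                    lengths[gj] = 0  # mark consumed
        m = 0
        for i in range(n):
            if lengths[i] > 0:
                lengths[m] = lengths[i]
                sites[m] = sites[i]
                m += 1
        n = m

    if k_minus > 0.0:
        n0 = n
        for i in range(n0):
            mlen = lengths[i]
            if mlen >= 2:
                p = k_minus * (mlen - 1) * dt
                if p > 1.0:
                    p = 1.0
                    clamp += 1
                if rng.random() < p:
                    b = rng.integers(1, mlen)  # left fragment keeps b monomers
                    lengths[n] = mlen - b
                    sites[n] = sites[i]
                    lengths[i] = b
                    n += 1

    if h > 0.0:
        for i in range(n):
            p = h * dt
            if p > 1.0:
                p = 1.0
                clamp += 1
            if rng.random() < p:
                d = rng.integers(0, 8)
                s = sites[i]
                x = (s % side + _DX[d]) % side
                y = (s // side + _DY[d]) % side
                sites[i] = y * side + x
    return n, clamp


@njit(cache=True)
def run_kernel(lengths, sites, n, n_sites, side, k_plus, k_minus, h, dt, rng,
               n_steps, strand_record):
    """Run ``n_steps`` consecutive steps, recording the strand count after each."""
    clamp_total = 0
    for t in range(n_steps):
        n, clamp = step_kernel(
            lengths, sites, n, n_sites, side, k_plus, k_minus, h, dt, rng
        )
        clamp_total += clamp
        strand_record[t] = n
    return n, clamp_total
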