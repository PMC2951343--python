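"""Numba-compiled inner loops of the evolutionary process.

These kernels operate on flat arrays (one row per lattice site / edge) and a
``numpy.random.Generator`` whose draw order is fixed, so a run is bit-for-bit
reproducible from its seed.  All public semantics live in
:mod:`ipdevo.population`; nothing here should be called directly.

Layout conventions
------------------
* ``genes``: (N, L) float64, cooperation probabilities per player.
* ``edges``: (E, 2) int64 site indices, E = 4N on the Moore torus; the pair
  history ``hist`` (E, k) stores joint-outcome codes from the perspective of
  ``edges[e, 0]``, oldest first, with ``hlen`` valid entries.
* Outcome codes: 0 = CC, 1 = CD, 2 = DC, 3 = DD, own move first; the mirror
  view of the second endpoint swaps codes 1 and 2.
* ``payvec``: payoff to the focal player per outcome code, (R, S, T, P).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True, fastmath=False)
def _gene_idx(hist_e, h, k, mirrored):
    """Gene consulted given h rounds of shared history (h <= k)."""
    if h == 0:
        return 0
    off = 0
    for j in range(h):
        o = hist_e[j]
        if mirrored:
            o = ((o & 1) << 1) | (o >> 1)
        off = off * 4 + o
    return (4**h - 1) // 3 + off


@njit(cache=True, fastmath=False)
def play_phase(genes, scores, counts, edges, hist, hlen, k, payvec, rng):
    """One synchronous play phase: every edge plays exactly one round.

    All decisions read the pre-round pair states, so the (fixed) edge order
    cannot influence the outcome distribution.  Returns the number of C
    moves this update (2E moves total), for optional progress summaries.
    """
    E = edges.shape[0]
    n_coop = 0
    for e in range(E):
        a = edges[e, 0]
        b = edges[e, 1]
        h = hlen[e]
        ia = _gene_idx(hist[e], h, k, False)
        ib = _gene_idx(hist[e], h, k, True)
        ma = 0 if rng.random() < genes[a, ia] else 1
        mb = 0 if rng.random() < genes[b, ib] else 1
        oa = 2 * ma + mb
        ob = 2 * mb + ma
        scores[a] += payvec[oa]
        scores[b] += payvec[ob]
        counts[a, oa] += 1
        counts[b, ob] += 1
        n_coop += (1 - ma) + (1 - mb)
        if h < k:
            hist[e, h] = oa
            hlen[e] = h + 1
        else:
            for j in range(k - 1):
                hist[e, j] = hist[e, j + 1]
            hist[e, k - 1] = oa
    return n_coop


@njit(cache=True, fastmath=False)
def replacement_phase(
    genes,
    scores,
    counts,
    neighbors,
    incident_edges,
    hlen,
    org_of_site,
    well_mixed,
    r,
    p_mut,
    n_alleles,
    next_org,
    rng,
    birth_site,
    birth_parent,
    birth_genes,
    death_org,
    death_counts,
):
    """One replacement phase; returns the number of deaths/births.

    Every player is independently marked dead with probability ``r``; each
    vacancy is then filled by a mutated copy of a parent drawn in proportion
    to lifetime score from the surviving candidate pool (the 8 neighbours
    for spatial structure, all other survivors for well-mixed).  Players
    marked dead this update are never candidates, so sites can be filled in
    index order against the pre-replacement survivor set.  If a vacancy's
    whole spatial pool is dead, the parent is drawn uniformly from all
    survivors; in the (astronomically unlikely) event that nobody survives,
    remaining vacancies are left untouched.

    Newborns start with score 0, zero play counts and fresh pair states on
    all 8 incident edges.  ``p_mut`` is the per-gene probability that at
    least one Poisson mutation event hits (``1 - exp(-mu)``); a hit gene is
    redrawn uniformly from the ``n_alleles``-point lattice.

    Birth and death records are written to the caller-provided buffers.
    """
    N = genes.shape[0]
    L = genes.shape[1]
    dead = np.zeros(N, dtype=np.bool_)
    n_dead = 0
    for i in range(N):
        if rng.random() < r:
            dead[i] = True
            n_dead += 1
    if n_dead == 0:
        return 0
    n_alive = N - n_dead
    nb = 0
    for v in range(N):
        if not dead[v]:
            continue
        parent = -1
        if well_mixed:
            tot = 0.0
            for c in range(N):
                if c != v and not dead[c]:
                    tot += scores[c]
            if n_alive > 0:
                if tot > 0.0:
                    x = rng.random() * tot
                    acc = 0.0
                    for c in range(N):
                        if c != v and not dead[c]:
                            acc += scores[c]
                            if x < acc:
                                parent = c
                                break
                    if parent < 0:  # guard against float round-off at the tail
                        for c in range(N - 1, -1, -1):
                            if c != v and not dead[c]:
                                parent = c
                                break
                else:
                    m = int(rng.random() * n_alive)
                    if m >= n_alive:
                        m = n_alive - 1
                    for c in range(N):
                        if c != v and not dead[c]:
                            if m == 0:
                                parent = c
                                break
                            m -= 1
        else:
            tot = 0.0
            ncand = 0
            for j in range(8):
                c = neighbors[v, j]
                if not dead[c]:
                    tot += scores[c]
                    ncand += 1
            if ncand > 0:
                if tot > 0.0:
                    x = rng.random() * tot
                    acc = 0.0
                    for j in range(8):
                        c = neighbors[v, j]
                        if not dead[c]:
                            acc += scores[c]
                            if x < acc:
                                parent = c
                                break
                    if parent < 0:
                        for j in range(7, -1, -1):
                            c = neighbors[v, j]
                            if not dead[c]:
                                parent = c
                                break
                else:
                    m = int(rng.random() * ncand)
                    if m >= ncand:
                        m = ncand - 1
                    for j in range(8):
                        c = neighbors[v, j]
                        if not dead[c]:
                            if m == 0:
                                parent = c
                                break
                            m -= 1
            elif n_alive > 0:
                # whole neighbourhood dead: uniform fallback over survivors
                m = int(rng.random() * n_alive)
                if m >= n_alive:
                    m = n_alive - 1
                for c in range(N):
                    if not dead[c]:
                        if m == 0:
                            parent = c
                            break
                        m -= 1
        if parent < 0:
            continue  # no survivors anywhere; leave the site as is
        death_org[nb] = org_of_site[v]
        for q in range(4):
            death_counts[nb, q] = counts[v, q]
        birth_site[nb] = v
        birth_parent[nb] = org_of_site[parent]
        for g in range(L):
            val = genes[parent, g]
            if p_mut > 0.0 and rng.random() < p_mut:
                idx = int(rng.random() * n_alleles)
                if idx >= n_alleles:
                    idx = n_alleles - 1
                val = idx / (n_alleles - 1.0)
            birth_genes[nb, g] = val
            genes[v, g] = val
        scores[v] = 0.0
        for q in range(4):
            counts[v, q] = 0
        org_of_site[v] = next_org + nb
        for j in range(8):
            hlen[incident_edges[v, j]] = 0
        nb += 1
    return nb
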