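"""Numba kernels for the structured-coalescent simulator.

The event loop lives here so that the simulation-based composite likelihood
(tens of thousands of genealogies per evaluation) runs at compiled speed.
Time is measured in generations before present.  The demography is passed in
flattened piecewise-constant form: breakpoint times ``bk`` (``bk[0] == 0``,
``bk[-1]`` effectively infinite) and, for each interval ``[bk[i], bk[i+1])``,
deme sizes ``N0[i]``/``N1[i]``, backwards migration rates ``m01[i]`` (deme 0
-> deme 1) and ``m10[i]``, and a ``merged`` flag (1 once the two demes have
merged into the ancestral deme, whose size is then ``N0``).

Coalescence within a deme of diploid size N happens at rate k(k-1)/2 / (2N):
selfing strains are sampled as single haplotypes.
"""

import numpy as np
from numba import njit

__all__ = ["seed_rng", "sim_tree", "sim_sfs_batch"]


@njit(cache=True)
def seed_rng(seed):
    np.random.seed(seed)


@njit(cache=True)
def sim_tree(n0, n1, bk, N0, N1, m01, m10, merged):
    """Simulate one genealogy; no recombination.

    Returns ``(parent, node_time, jcnt, kcnt)`` over the ``2n - 1`` nodes:
    leaves ``0..n0-1`` are deme-0 samples, ``n0..n-1`` deme-1 samples,
    internal nodes are appended in coalescence order (the root is last).
    ``jcnt``/``kcnt`` give each node's descendant-leaf counts in deme 0 / 1.
    """
    n = n0 + n1
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, np.int64)
    node_time = np.zeros(n_nodes, np.float64)
    jcnt = np.zeros(n_nodes, np.int64)
    kcnt = np.zeros(n_nodes, np.int64)

    act = np.empty(n, np.int64)   # active lineage -> node id
    dem = np.empty(n, np.int64)   # active lineage -> deme
    for i in range(n0):
        act[i] = i
        dem[i] = 0
        jcnt[i] = 1
    for i in range(n1):
        act[n0 + i] = n0 + i
        dem[n0 + i] = 1
        kcnt[n0 + i] = 1

    na = n
    nxt = n
    t = 0.0
    iv = 0
    n_iv = len(bk) - 1
    if merged[0] == 1:
        for i in range(na):
            dem[i] = 0

    while na > 1:
        while iv + 1 < n_iv and t >= bk[iv + 1]:
            iv += 1
            if merged[iv] == 1:
                for i in range(na):
                    dem[i] = 0
        k0 = 0
        for i in range(na):
            if dem[i] == 0:
                k0 += 1
        k1 = na - k0
        c0 = k0 * (k0 - 1) / 2.0 / (2.0 * N0[iv])
        if merged[iv] == 0:
            c1 = k1 * (k1 - 1) / 2.0 / (2.0 * N1[iv])
            r01 = k0 * m01[iv]
            r10 = k1 * m10[iv]
        else:
            c1 = 0.0
            r01 = 0.0
            r10 = 0.0
        tot = c0 + c1 + r01 + r10
        t_next = bk[iv + 1]
        if tot <= 0.0:
            t = t_next
            continue
        dt = np.random.exponential(1.0 / tot)
        if t + dt >= t_next:
            t = t_next
            continue
        t = t + dt
        u = np.random.random() * tot
        if u < c0 + c1:
            d = 0 if u < c0 else 1
            kd = k0 if d == 0 else k1
            a = np.random.randint(kd)
            b = np.random.randint(kd - 1)
            if b >= a:
                b += 1
            # map deme-local indices to active slots
            ia = -1
            ib = -1
            seen = 0
            for i in range(na):
                if dem[i] == d:
                    if seen == a:
                        ia = i
                    if seen == b:
                        ib = i
                    seen += 1
            ca = act[ia]
            cb = act[ib]
            node_time[nxt] = t
            parent[ca] = nxt
            parent[cb] = nxt
            jcnt[nxt] = jcnt[ca] + jcnt[cb]
            kcnt[nxt] = kcnt[ca] + kcnt[cb]
            act[ia] = nxt
            act[ib] = act[na - 1]
            dem[ib] = dem[na - 1]
            nxt += 1
            na -= 1
        else:
            # migration: flip one lineage's deme (backwards in time)
            src = 0 if u < c0 + c1 + r01 else 1
            ks = k0 if src == 0 else k1
            a = np.random.randint(ks)
            seen = 0
            for i in range(na):
                if dem[i] == src:
                    if seen == a:
                        dem[i] = 1 - src
                        break
                    seen += 1
    return parent, node_time, jcnt, kcnt


@njit(cache=True)
def sim_sfs_batch(n_sims, n0, n1, bk, N0, N1, m01, m10, merged, seed):
    """Accumulate the branch-area joint SFS over ``n_sims`` genealogies.

    Each non-root node contributes its branch length to the cell indexed by
    its descendant-leaf counts ``(j, k)``; mutations are Poisson on branch
    area, so the normalized accumulation estimates the expected (unfolded)
    joint SFS of segregating sites.
    """
    np.random.seed(seed)
    sfs = np.zeros((n0 + 1, n1 + 1), np.float64)
    n_nodes = 2 * (n0 + n1) - 1
    for _ in range(n_sims):
        parent, node_time, jcnt, kcnt = sim_tree(n0, n1, bk, N0, N1, m01, m10, merged)
        for u in range(n_nodes - 1):
            sfs[jcnt[u], kcnt[u]] += node_time[parent[u]] - node_time[u]
    return sfs
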