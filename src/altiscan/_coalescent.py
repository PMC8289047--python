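"""Structured-coalescent kernels (numba-compiled).

All kernels operate on the piecewise-constant epoch table produced by
:meth:`altiscan.types.DemographySpec.to_epochs`: rows ``(t_start, N0, N1, m0,
m1)``, with ``N1 <= 0`` marking the lowland deme inactive (its lineages are
absorbed into deme 0 on epoch entry) and ``m0``/``m1`` the backward
per-lineage trace rates.  Node indexing follows the standard convention that
leaves occupy ``0..n-1`` (deme-0 leaves first) and internal nodes are created
in coalescence order, so every parent index exceeds its children's indices.
"""

import numpy as np
from numba import njit

__all__ = [
    "sim_tree",
    "leaf_counts",
    "total_branch_length",
    "accumulate_sfs_weights",
    "genealogy_total_lengths",
    "carriers_for_sites",
    "place_poisson_mutations",
]


@njit(cache=True)
def _sim_tree_core(n0, n1, epochs):
    n = n0 + n1
    n_nodes = 2 * n - 1
    parent = np.full(n_nodes, -1, dtype=np.int64)
    ntime = np.zeros(n_nodes, dtype=np.float64)
    # active lineage list
    node = np.empty(n, dtype=np.int64)
    deme = np.empty(n, dtype=np.int64)
    for i in range(n0):
        node[i] = i
        deme[i] = 0
    for i in range(n1):
        node[n0 + i] = n0 + i
        deme[n0 + i] = 1
    k = n
    t = 0.0
    ep = 0
    E = epochs.shape[0]
    next_internal = n
    n_mig = 0
    while k > 1:
        N0 = epochs[ep, 1]
        N1 = epochs[ep, 2]
        m0 = epochs[ep, 3]
        m1 = epochs[ep, 4]
        if N1 <= 0.0:
            for i in range(k):
                deme[i] = 0
        k0 = 0
        for i in range(k):
            if deme[i] == 0:
                k0 += 1
        k1 = k - k0
        rate_c0 = k0 * (k0 - 1) / (4.0 * N0)
        rate_c1 = k1 * (k1 - 1) / (4.0 * N1) if N1 > 0.0 else 0.0
        rate_m0 = k0 * m0
        rate_m1 = k1 * m1
        rate = rate_c0 + rate_c1 + rate_m0 + rate_m1
        nb = epochs[ep + 1, 0] if ep + 1 < E else np.inf
        if rate <= 0.0:
            t = nb
            ep += 1
            continue
        dt = np.random.exponential(1.0 / rate)
        if t + dt >= nb:
            t = nb
            ep += 1
            continue
        t += dt
        u = np.random.random() * rate
        if u < rate_c0 or u < rate_c0 + rate_c1:
            d = 0 if u < rate_c0 else 1
            kd = k0 if d == 0 else k1
            a = np.random.randint(kd)
            b = np.random.randint(kd - 1)
            if b >= a:
                b += 1
            # map within-deme indices to lineage-list indices
            ia = -1
            ib = -1
            c = 0
            for i in range(k):
                if deme[i] == d:
                    if c == a:
                        ia = i
                    if c == b:
                        ib = i
                    c += 1
            v = next_internal
            next_internal += 1
            parent[node[ia]] = v
            parent[node[ib]] = v
            ntime[v] = t
            node[ia] = v
            # remove ib by swapping in the tail
            node[ib] = node[k - 1]
            deme[ib] = deme[k - 1]
            k -= 1
        else:
            # migration event: deme 0 -> 1 or 1 -> 0 (backward in time)
            d = 0 if u < rate_c0 + rate_c1 + rate_m0 else 1
            kd = k0 if d == 0 else k1
            a = np.random.randint(kd)
            c = 0
            for i in range(k):
                if deme[i] == d:
                    if c == a:
                        deme[i] = 1 - d
                        break
                    c += 1
            n_mig += 1
    return parent, ntime, n_mig


@njit(cache=True)
def sim_tree(n0, n1, epochs, seed):
    """Simulate one genealogy; returns (parent, node_time, n_migrations)."""
    np.random.seed(seed)
    return _sim_tree_core(n0, n1, epochs)


@njit(cache=True)
def leaf_counts(parent, n0, n1):
    """Per-node counts of deme-0 and deme-1 leaves beneath each node."""
    n_nodes = parent.shape[0]
    c0 = np.zeros(n_nodes, dtype=np.int64)
    c1 = np.zeros(n_nodes, dtype=np.int64)
    for i in range(n0):
        c0[i] = 1
    for i in range(n0, n0 + n1):
        c1[i] = 1
    for v in range(n_nodes - 1):
        p = parent[v]
        c0[p] += c0[v]
        c1[p] += c1[v]
    return c0, c1


@njit(cache=True)
def total_branch_length(parent, ntime):
    tot = 0.0
    for v in range(parent.shape[0]):
        p = parent[v]
        if p >= 0:
            tot += ntime[p] - ntime[v]
    return tot


@njit(cache=True)
def accumulate_sfs_weights(n0, n1, epochs, n_reps, seed, W):
    """Add branch-length weights to the unfolded joint-SFS array ``W``.

    ``W[i, j]`` accumulates total branch length (over replicates) subtending
    exactly ``i`` deme-0 and ``j`` deme-1 leaves; a mutation falling on such a
    branch yields a derived-allele configuration ``(i, j)``.  Replicate ``r``
    re-seeds at ``seed + r`` so the genealogy stream is common across
    parameter values (common random numbers).
    """
    for r in range(n_reps):
        np.random.seed(seed + r)
        parent, ntime, _ = _sim_tree_core(n0, n1, epochs)
        c0, c1 = leaf_counts(parent, n0, n1)
        for v in range(parent.shape[0]):
            p = parent[v]
            if p >= 0:
                W[c0[v], c1[v]] += ntime[p] - ntime[v]


@njit(cache=True)
def _carriers_below(parent, node, n_leaves, out):
    """Mark leaves beneath ``node`` in the 0/1 array ``out``."""
    n_nodes = parent.shape[0]
    below = np.zeros(n_nodes, dtype=np.uint8)
    below[node] = 1
    # parents precede children never: parent index > child index, so walk down
    for v in range(node - 1, -1, -1):
        if parent[v] >= 0 and below[parent[v]] == 1:
            below[v] = 1
    for i in range(n_leaves):
        out[i] = below[i]


@njit(cache=True)
def genealogy_total_lengths(n0, n1, epochs, n_reps, seed):
    """Total branch length (generations) of ``n_reps`` genealogies seeded
    ``seed + r``; the trees are reproducible from those seeds."""
    out = np.empty(n_reps, dtype=np.float64)
    for r in range(n_reps):
        np.random.seed(seed + r)
        parent, ntime, _ = _sim_tree_core(n0, n1, epochs)
        tot = 0.0
        for v in range(parent.shape[0]):
            if parent[v] >= 0:
                tot += ntime[parent[v]] - ntime[v]
        out[r] = tot
    return out


@njit(cache=True)
def carriers_for_sites(n0, n1, epochs, tree_seeds, branch_seeds):
    """Derived-allele carriers for one mutation per listed genealogy.

    Each site ``s`` re-simulates the genealogy from ``tree_seeds[s]`` and
    places a single mutation on a branch chosen proportionally to length
    (randomness from ``branch_seeds[s]``, so repeated genealogies get
    independent branches).  Returns ``(n_sites, n0+n1)`` uint8 carrier flags.
    """
    n = n0 + n1
    n_sites = tree_seeds.shape[0]
    out = np.zeros((n_sites, n), dtype=np.uint8)
    for s in range(n_sites):
        np.random.seed(tree_seeds[s])
        parent, ntime, _ = _sim_tree_core(n0, n1, epochs)
        n_nodes = parent.shape[0]
        tot = 0.0
        for v in range(n_nodes):
            if parent[v] >= 0:
                tot += ntime[parent[v]] - ntime[v]
        np.random.seed(branch_seeds[s])
        u = np.random.random() * tot
        acc = 0.0
        chosen = n_nodes - 2
        for v in range(n_nodes):
            if parent[v] >= 0:
                acc += ntime[parent[v]] - ntime[v]
                if u < acc:
                    chosen = v
                    break
        _carriers_below(parent, chosen, n, out[s])
    return out


@njit(cache=True)
def place_poisson_mutations(parent, ntime, rate_per_gen, seed):
    """Poisson infinite-sites mutations on a genealogy.

    ``rate_per_gen`` is mu * locus_length.  Returns an ``(n_mut, n_leaves)``
    uint8 carrier matrix, mutations in random branch order.
    """
    np.random.seed(seed)
    n_nodes = parent.shape[0]
    n_leaves = (n_nodes + 1) // 2
    blen = np.zeros(n_nodes, dtype=np.float64)
    tot = 0.0
    for v in range(n_nodes):
        if parent[v] >= 0:
            blen[v] = ntime[parent[v]] - ntime[v]
            tot += blen[v]
    n_mut = np.random.poisson(rate_per_gen * tot)
    out = np.zeros((n_mut, n_leaves), dtype=np.uint8)
    for m in range(n_mut):
        u = np.random.random() * tot
        acc = 0.0
        chosen = n_nodes - 2
        for v in range(n_nodes):
            if parent[v] >= 0:
                acc += blen[v]
                if u < acc:
                    chosen = v
                    break
        _carriers_below(parent, chosen, n_leaves, out[m])
    return out
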