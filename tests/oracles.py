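"""Independent reference implementations used only to check the package.

These deliberately use different algorithms from the library: union-find for
clustering, explicit hypergeometric enumeration for the Fisher test, direct
ECDF scanning for KS, the step-up formula written out for BH.
"""

from math import comb

import numpy as np


def union_find_clusters(positions, max_gap):
    """Transitive closure of |p_i - p_j| <= max_gap via union-find."""
    positions = list(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj

    for i in range(n):
        for j in range(i + 1, n):
            if abs(positions[i] - positions[j]) <= max_gap:
                union(i, j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(sorted(g) for g in groups.values())


def fisher_two_sided(a, b, c, d):
    """Exact two-sided Fisher p by full enumeration at fixed margins."""
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def table_prob(x):        # x = top-left cell
        return (comb(r1, x) * comb(r2, c1 - x)) / comb(n, c1)

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = table_prob(a)
    total = 0.0
    for x in range(lo, hi + 1):
        p = table_prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def bh_step_up(pvalues):
    """Benjamini-Hochberg written out from the definition."""
    p = np.asarray(pvalues, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    adj = np.empty(m)
    running_min = 1.0
    for rank_from_top in range(m - 1, -1, -1):
        i = order[rank_from_top]
        val = p[i] * m / (rank_from_top + 1)
        running_min = min(running_min, val)
        adj[i] = min(running_min, 1.0)
    return adj


def ks_statistic(a, b):
    """Max ECDF gap by scanning all observed values."""
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    values = np.concatenate([a, b])
    d = 0.0
    for v in values:
        fa = np.searchsorted(a, v, side="right") / len(a)
        fb = np.searchsorted(b, v, side="right") / len(b)
        d = max(d, abs(fa - fb))
    return d


def py_run_brute(seq, i, good):
    """Length of the contiguous run of ``good`` bases containing index i."""
    if seq[i] not in good:
        raise ValueError("center not in alphabet")
    n = 1
    j = i - 1
    while j >= 0 and seq[j] in good:
        n += 1
        j -= 1
    j = i + 1
    while j < len(seq) and seq[j] in good:
        n += 1
        j += 1
    return n
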