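"""Independent brute-force oracles used to cross-check the pipeline's
statistics and clustering. These deliberately avoid the implementation
paths they verify."""
import itertools
from math import comb

import numpy as np
from scipy.stats import rankdata


def hamming_matches(seq: str, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """Naive sliding-window Hamming scan."""
    m = len(pattern)
    out = []
    for i in range(len(seq) - m + 1):
        mm = sum(a != b for a, b in zip(seq[i:i + m], pattern))
        if mm <= max_mm:
            out.append((i, mm))
    return out


def single_linkage_clusters(positions, link_dist: int) -> list[tuple[int, ...]]:
    """Connected components of the graph with an edge iff |a-b| <= link_dist,
    via union-find on the position multiset."""
    pos = list(positions)
    n = len(pos)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if abs(pos[i] - pos[j]) <= link_dist:
                parent[find(i)] = find(j)
    comps = {}
    for i in range(n):
        comps.setdefault(find(i), []).append(pos[i])
    return sorted(tuple(sorted(c)) for c in comps.values())


def fisher_exact_two_sided(table) -> float:
    """Two-sided Fisher p by full hypergeometric enumeration at fixed
    margins, with exact integer arithmetic."""
    (a, b), (c, d) = table
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2
    if n == 0:
        return 1.0
    denom = comb(n, c1)
    p_obs = comb(r1, a) * comb(r2, c)
    total = 0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = comb(r1, x) * comb(r2, c1 - x)
        if px <= p_obs:
            total += px
    return total / denom


def wilcoxon_exact_two_sided(diffs) -> float:
    """Two-sided signed-rank p by exhaustive sign-assignment enumeration
    (requires non-zero, tie-free |differences|)."""
    d = np.asarray(diffs, float)
    n = len(d)
    ranks = rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    m = n * (n + 1) / 2
    ws = np.array([
        sum(r for s, r in zip(signs, ranks) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ])
    p = (np.sum(ws <= min(w_obs, m - w_obs))
         + np.sum(ws >= max(w_obs, m - w_obs))) / len(ws)
    return float(min(p, 1.0))
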