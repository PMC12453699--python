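"""Independent brute-force references used as test oracles.

Everything here is deliberately naive and self-contained: full O(n^2)
distance tables computed with explicit loops, a textbook Kruskal MST built
by sorting edges, and an adjusted Rand index obtained by enumerating point
pairs.  None of it shares code with the package implementation.
"""

from __future__ import annotations

import math


def _dist(p, q):
    return math.sqrt(sum((a - b) ** 2 for a, b in zip(p, q)))


def naive_apcd(cluster_points, d):
    """APCD per member via the printed formula, plain loops."""
    m = len(cluster_points)
    out = []
    for i in range(m):
        terms = []
        for j in range(m):
            if i == j:
                continue
            dij = _dist(cluster_points[i], cluster_points[j])
            if dij == 0.0:
                terms.append(math.inf)
            else:
                terms.append((1.0 / dij) ** d)
        mean = sum(terms) / (m - 1)
        out.append(0.0 if math.isinf(mean) else mean ** (-1.0 / d))
    return out


def _kruskal(n_nodes, edges):
    """Textbook Kruskal by edge sorting; edges are (w, i, j) tuples."""
    parent = list(range(n_nodes))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    tree = []
    for w, i, j in sorted(edges):
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[ri] = rj
            tree.append((w, i, j))
    return tree


def naive_dbcv(points, labels, noise_label=-1, dsc_mode="all", dspc_mode="all"):
    """Full DBCV by the printed definitions, loops and Kruskal only.

    Returns the overall index.  Assumes >= 2 clusters of >= 2 members.
    """
    points = [list(map(float, p)) for p in points]
    labels = list(labels)
    n = len(points)
    d = len(points[0])
    clusters = sorted({l for l in labels if l != noise_label})
    members = {c: [i for i, l in enumerate(labels) if l == c] for c in clusters}

    apcd = {}
    for c in clusters:
        vals = naive_apcd([points[i] for i in members[c]], d)
        for i, v in zip(members[c], vals):
            apcd[i] = v

    def mrd(i, j):
        return max(apcd[i], apcd[j], _dist(points[i], points[j]))

    dsc = {}
    internal = {}
    for c in clusters:
        idx = members[c]
        edges = [
            (mrd(idx[a], idx[b]), a, b)
            for a in range(len(idx))
            for b in range(a + 1, len(idx))
        ]
        tree = _kruskal(len(idx), edges)
        deg = [0] * len(idx)
        for _, i, j in tree:
            deg[i] += 1
            deg[j] += 1
        internal[c] = [idx[a] for a in range(len(idx)) if deg[a] >= 2] or list(idx)
        weights = [w for w, i, j in tree]
        if dsc_mode == "internal":
            inner = [w for w, i, j in tree if deg[i] >= 2 and deg[j] >= 2]
            weights = inner or weights
        dsc[c] = max(weights)

    overall = 0.0
    for c in clusters:
        dspcs = []
        for c2 in clusters:
            if c2 == c:
                continue
            if dspc_mode == "internal":
                pool_a, pool_b = internal[c], internal[c2]
            else:
                pool_a, pool_b = members[c], members[c2]
            dspcs.append(min(mrd(i, j) for i in pool_a for j in pool_b))
        sep = min(dspcs)
        vc = (sep - dsc[c]) / max(sep, dsc[c])
        overall += (len(members[c]) / n) * vc
    return overall


def pair_enumeration_ari(labels_a, labels_b):
    """ARI by explicit enumeration of the C(n,2) point pairs."""
    a, b = list(labels_a), list(labels_b)
    n = len(a)
    n11 = n10 = n01 = n00 = 0
    for i in range(n):
        for j in range(i + 1, n):
            same_a = a[i] == a[j]
            same_b = b[i] == b[j]
            if same_a and same_b:
                n11 += 1
            elif same_a:
                n10 += 1
            elif same_b:
                n01 += 1
            else:
                n00 += 1
    total = n * (n - 1) // 2
    if total == 0:
        return 1.0
    sum_a = n11 + n10  # same-cluster pairs in a
    sum_b = n11 + n01
    expected = sum_a * sum_b / total
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return (n11 - expected) / (max_index - expected)


def set_partitions(n):
    """All partitions of range(n) as label tuples (restricted growth strings)."""
    out = []

    def rec(i, labels, k):
        if i == n:
            out.append(tuple(labels))
            return
        for lab in range(k + 1):
            rec(i + 1, labels + [lab], max(k, lab + 1))

    rec(0, [], 0)
    return out
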