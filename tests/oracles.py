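"""Independent brute-force oracles used to cross-check the implementation.

Everything here works from plain edge lists and elementary enumeration —
no imports from the package's path or statistics code — so agreement with
the package is a genuine dual-route check.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

SIGN = {"positive": 1, "negative": -1, "neutral": 0}


def brute_force_paths(edges, source, destination, require_signed, max_length):
    """All minimal-length simple typed paths by exhaustive DFS.

    ``edges`` is a list of (u, v, type-label) triples (duplicates ignored).
    Returns (paths, T_list, W_list, V) where each path is
    (node tuple, label tuple); V is a Fraction.
    """
    edge_set = sorted(set(edges))
    out_deg = {}
    adj = {}
    for u, v, lab in edge_set:
        out_deg[u] = out_deg.get(u, 0) + 1
        adj.setdefault(u, []).append((v, lab))

    found = []

    def rec(node, nodes, labels):
        if len(labels) > max_length:
            return
        if node == destination and labels:
            found.append((tuple(nodes), tuple(labels)))
            return
        for v, lab in adj.get(node, []):
            if v in nodes:
                continue
            rec(v, nodes + [v], labels + [lab])

    rec(source, [source], [])

    if require_signed:
        found = [p for p in found if any(SIGN[l] != 0 for l in p[1])]
    if not found:
        return [], [], [], Fraction(0)
    min_len = min(len(p[1]) for p in found)
    found = sorted(p for p in found if len(p[1]) == min_len)
    ts, ws = [], []
    for nodes, labels in found:
        t = 1
        for l in labels:
            if SIGN[l]:
                t *= SIGN[l]
        w = Fraction(1)
        for g in nodes[:-1]:
            w /= out_deg[g]
        ts.append(t)
        ws.append(w)
    v = sum(t * w for t, w in zip(ts, ws))
    return found, ts, ws, v


def exact_hypergeom_upper(N, K, n, k):
    """P(X >= k) by direct combinatorial summation."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
    ) / total


def exact_ranksum_greater(x, y):
    """One-tailed (x stochastically greater) rank-sum p by enumerating all
    C(n1+n2, n1) assignments of the pooled ranks; assumes no ties."""
    pooled = sorted(x + y, reverse=True)
    assert len(set(pooled)) == len(pooled), "oracle assumes no ties"
    ranks = {v: i + 1 for i, v in enumerate(sorted(pooled))}
    n1 = len(x)
    observed = sum(ranks[v] for v in x)
    count = total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), n1):
        total += 1
        if sum(combo) >= observed:
            count += 1
    return count / total


def random_typed_network(rng, max_genes=12):
    """A small random typed edge list for oracle-equivalence checks."""
    n = int(rng.integers(4, max_genes + 1))
    genes = [f"g{i}" for i in range(n)]
    n_edges = int(rng.integers(n, 3 * n + 1))
    labels = ["positive", "negative", "neutral"]
    edges = set()
    for _ in range(n_edges):
        u, v = rng.choice(n, size=2, replace=False)
        edges.add((genes[u], genes[v], labels[rng.integers(3)]))
    return genes, sorted(edges)
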