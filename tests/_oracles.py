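"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately naive: subset enumeration, hand-rolled
union-find, exact rational arithmetic.  None of it shares code paths with
the package.
"""

from __future__ import annotations

from fractions import Fraction
from itertools import combinations
from math import comb, factorial


def brute_components(nodes: list, edges: set[frozenset]) -> list[set]:
    """Connected components by union-find over an explicit edge set."""
    parent = {v: v for v in nodes}

    def find(v):
        while parent[v] != v:
            parent[v] = parent[parent[v]]
            v = parent[v]
        return v

    for e in edges:
        a, b = tuple(e)
        if a in parent and b in parent:
            parent[find(a)] = find(b)
    comps: dict = {}
    for v in nodes:
        comps.setdefault(find(v), set()).add(v)
    return list(comps.values())


def brute_mnc(nodes: list, edges: set[frozenset]) -> dict:
    """Largest neighborhood-component size per node, by subset enumeration."""
    adj = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)
    out = {}
    for v in nodes:
        nbrs = sorted(adj[v])
        if not nbrs:
            out[v] = 0
            continue
        sub_edges = {e for e in edges if set(e) <= set(nbrs)}
        out[v] = max(len(c) for c in brute_components(nbrs, sub_edges))
    return out


def brute_maximal_cliques(nodes: list, edges: set[frozenset]) -> list[frozenset]:
    """All maximal cliques by checking every subset (graphs must be tiny)."""
    adj = {v: set() for v in nodes}
    for e in edges:
        a, b = tuple(e)
        adj[a].add(b)
        adj[b].add(a)

    def is_clique(sub):
        return all(b in adj[a] for a, b in combinations(sub, 2))

    cliques = []
    n = len(nodes)
    for r in range(1, n + 1):
        for sub in combinations(nodes, r):
            if is_clique(sub):
                cliques.append(frozenset(sub))
    return [
        c for c in cliques
        if not any(c < other for other in cliques)
    ]


def brute_mcc(nodes: list, edges: set[frozenset]) -> dict:
    """MCC per node via the brute-force maximal-clique enumeration.

    Size-1 maximal cliques (isolated nodes) contribute 0, matching the
    convention that a node without interactions has no clique centrality.
    """
    out = {v: 0 for v in nodes}
    for c in brute_maximal_cliques(nodes, edges):
        if len(c) == 1:
            continue
        for v in c:
            out[v] += factorial(len(c) - 1)
    return out


def exact_epc(nodes: list, edges: list[frozenset], p: Fraction) -> dict:
    """Exact expected component size per node by enumerating all 2^m edge
    subsets; also returns the exact variance (for Monte-Carlo SE bounds)."""
    m = len(edges)
    e1 = {v: Fraction(0) for v in nodes}
    e2 = {v: Fraction(0) for v in nodes}
    for mask in range(2 ** m):
        kept = {edges[i] for i in range(m) if mask >> i & 1}
        k = len(kept)
        prob = p**k * (1 - p) ** (m - k)
        for c in brute_components(nodes, kept):
            for v in c:
                e1[v] += prob * len(c)
                e2[v] += prob * len(c) ** 2
    mean = {v: e1[v] for v in nodes}
    var = {v: e2[v] - e1[v] ** 2 for v in nodes}
    return {"mean": mean, "var": var}


def exact_hypergeom_tail(k: int, N: int, K: int, n: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), exact rational arithmetic."""
    total = comb(N, n)
    acc = 0
    for i in range(k, min(K, n) + 1):
        acc += comb(K, i) * comb(N - K, n - i)
    return Fraction(acc, total)


def brute_bh(pvals: list[float]) -> list[float]:
    """Step-up Benjamini-Hochberg straight from the definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    q = [0.0] * m
    running = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        running = min(running, pvals[i] * m / rank_from_top)
        q[i] = running
    return q
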