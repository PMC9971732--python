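"""MCODE molecular-complex detection.

The algorithm has three phases:

1. **Vertex weighting.**  For each vertex v, take the closed neighborhood
   N[v], find its highest k-core (the core with maximum k), and set
   w(v) = k_max * density(highest k-core).  Vertices with degree below
   ``degree_cutoff`` get weight 0.  Density is 2m / (n (n-1)), loops
   excluded.
2. **Complex prediction.**  Starting from the highest-weight unassigned
   vertex (the complex's *seed node*), grow outward breadth-first, admitting
   an unassigned neighbor u whenever w(u) >= w(seed) * (1 - node_score_cutoff),
   up to ``max_depth`` levels from the seed.  Each vertex belongs to at most
   one complex (fluff mode, which would allow overlap, is not supported).
3. **Post-processing.**  Complexes that do not contain a 2-core are
   discarded; the haircut then iteratively strips singly-connected vertices.
   The complex score, density * size, is computed after post-processing.

Complexes are ranked by descending score, ties broken by descending size and
then lexicographic seed name.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx

from .errors import ValidationError
from .targets import GeneSet

__all__ = ["MCODEParams", "ModuleResult", "vertex_weights", "find_modules"]


@dataclass(frozen=True)
class MCODEParams:
    """MCODE tuning parameters, fixed to the conventional defaults.

    ``node_score_cutoff`` is the fractional weight drop tolerated when
    growing a complex from its seed; ``haircut`` strips singly-connected
    periphery; ``fluff`` (overlapping complexes) is not supported and must
    stay False.
    """

    include_loops: bool = False
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    haircut: bool = True
    fluff: bool = False
    fluff_density: float = 0.1
    k_core: int = 2
    max_depth: int = 100

    def __post_init__(self):
        if not 0.0 <= self.node_score_cutoff <= 1.0:
            raise ValidationError("node_score_cutoff must be in [0, 1]")
        if not 0.0 <= self.fluff_density <= 1.0:
            raise ValidationError("fluff_density must be in [0, 1]")
        if self.degree_cutoff < 0 or self.k_core < 0 or self.max_depth < 1:
            raise ValidationError("degree_cutoff/k_core >= 0 and max_depth >= 1 required")
        if self.fluff:
            raise ValidationError("fluff mode (overlapping complexes) is not supported")
        if self.include_loops:
            raise ValidationError("include_loops is not supported (graphs are simple)")


@dataclass(frozen=True)
class ModuleResult:
    """One predicted complex: member genes, growth seed, score, rank."""

    nodes: GeneSet
    seed: str
    score: float
    rank: int


def _density(h: nx.Graph) -> float:
    n = h.number_of_nodes()
    if n < 2:
        return 0.0
    return 2.0 * h.number_of_edges() / (n * (n - 1))


def vertex_weights(g: nx.Graph, params: MCODEParams | None = None) -> dict[str, float]:
    """k-core-based MCODE vertex weights (0 below the degree cutoff)."""
    params = params or MCODEParams()
    weights: dict[str, float] = {}
    for v in g.nodes:
        if g.degree(v) < params.degree_cutoff:
            weights[v] = 0.0
            continue
        closed = list(g.neighbors(v)) + [v]
        h = g.subgraph(closed)
        core = nx.core_number(h)
        k_max = max(core.values())
        top = h.subgraph([u for u, k in core.items() if k == k_max])
        weights[v] = k_max * _density(top)
    return weights


def _grow(g: nx.Graph, seed: str, w: dict[str, float], assigned: set[str],
          threshold: float, max_depth: int) -> set[str]:
    complex_nodes = {seed}
    frontier = [seed]
    depth = 0
    while frontier and depth < max_depth:
        nxt = []
        for v in frontier:
            for u in g.neighbors(v):
                if u in assigned or u in complex_nodes:
                    continue
                if w[u] >= threshold:
                    complex_nodes.add(u)
                    nxt.append(u)
        frontier = nxt
        depth += 1
    return complex_nodes


def find_modules(g: nx.Graph, params: MCODEParams | None = None) -> list[ModuleResult]:
    """Predict node-disjoint complexes and rank them by density * size."""
    params = params or MCODEParams()
    w = vertex_weights(g, params)
    order = sorted(g.nodes, key=lambda v: (-w[v], v))
    assigned: set[str] = set()
    raw: list[tuple[str, set[str]]] = []
    for seed in order:
        if seed in assigned or w[seed] <= 0.0:
            continue
        threshold = w[seed] * (1.0 - params.node_score_cutoff)
        nodes = _grow(g, seed, w, assigned, threshold, params.max_depth)
        assigned |= nodes
        raw.append((seed, nodes))

    results: list[tuple[float, int, str, frozenset]] = []
    for seed, nodes in raw:
        h = g.subgraph(nodes)
        core2 = nx.k_core(h, params.k_core)
        if core2.number_of_nodes() == 0:
            continue  # complex lacks a 2-core
        final = h
        if params.haircut:
            # iterated removal of singly-connected vertices == the 2-core
            final = nx.k_core(h, 2)
        if final.number_of_nodes() < 2:
            continue
        seed_node = seed if seed in final else min(
            final.nodes, key=lambda v: (-w[v], v)
        )
        score = _density(final) * final.number_of_nodes()
        results.append((score, final.number_of_nodes(), seed_node, frozenset(final.nodes)))

    results.sort(key=lambda r: (-r[0], -r[1], r[2]))
    out = []
    for rank, (score, _size, seed_node, nodes) in enumerate(results, 1):
        gset = GeneSet(
            f"module_{rank}", nodes, {v: frozenset({"mcode"}) for v in nodes}
        )
        out.append(ModuleResult(nodes=gset, seed=seed_node, score=score, rank=rank))
    return out
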