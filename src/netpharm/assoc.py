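"""Association-based expansion of an intersection gene set.

Given a weighted functional-association network and a seed set, rank the
non-seed genes by a degree-normalized seed-connectivity score

    score(g) = sum_{s in seeds, (g,s) in E} w(g,s) / sqrt(deg(g))

and return the top k.  The square-root degree penalty damps promiscuous
hubs that touch everything, the same intuition behind normalized adjacency
operators in label propagation, while remaining deterministic and
brute-force checkable.  Candidates with zero score are never returned.
"""

from __future__ import annotations

import math
from pathlib import Path

import networkx as nx

from .errors import SeedsNotInNetworkError, ValidationError
from .targets import GeneSet

__all__ = ["expand_related", "association_scores", "read_association_tsv"]


def association_scores(net: nx.Graph, seeds: GeneSet) -> dict[str, float]:
    """Seed-connectivity score for every non-seed node of the network."""
    seed_in_net = [s for s in seeds.members if net.has_node(s)]
    if not seed_in_net:
        raise SeedsNotInNetworkError(
            f"none of the {len(seeds)} seeds is present in the association network"
        )
    seed_set = set(seed_in_net)
    scores: dict[str, float] = {}
    for g in net.nodes:
        if g in seeds.members:
            continue
        total = 0.0
        for s, attrs in net[g].items():
            if s in seed_set:
                total += float(attrs.get("weight", 1.0))
        if total > 0:
            scores[g] = total / math.sqrt(net.degree(g))
    return scores


def expand_related(net: nx.Graph, seeds: GeneSet, k: int = 20) -> GeneSet:
    """Return the top-``k`` non-seed genes most associated with the seed set.

    Results are ranked by descending score with lexicographic tie-breaking,
    are disjoint from the seeds, and include only positively scored
    candidates (fewer than ``k`` may be returned).
    """
    if k < 1:
        raise ValidationError(f"k must be >= 1, got {k}")
    scores = association_scores(net, seeds)
    ranked = sorted(scores.items(), key=lambda item: (-item[1], item[0]))
    chosen = [g for g, _ in ranked[:k]]
    return GeneSet(
        f"associated({seeds.label})",
        frozenset(chosen),
        {g: frozenset({"association_expansion"}) for g in chosen},
    )


def read_association_tsv(path: str | Path) -> nx.Graph:
    """Read a 3-column TSV (geneA, geneB, weight) association network.

    Weights must be positive; duplicate pairs keep the maximum weight;
    self-loops are rejected.
    """
    g = nx.Graph()
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValidationError(f"{path}:{i}: expected 3 tab-separated columns")
        a, b = parts[0].strip().upper(), parts[1].strip().upper()
        try:
            w = float(parts[2])
        except ValueError as exc:
            raise ValidationError(f"{path}:{i}: bad weight {parts[2]!r}") from exc
        if w <= 0:
            raise ValidationError(f"{path}:{i}: association weight must be > 0")
        if a == b:
            raise ValidationError(f"{path}:{i}: self-loop {a}")
        if g.has_edge(a, b):
            g[a][b]["weight"] = max(g[a][b]["weight"], w)
        else:
            g.add_edge(a, b, weight=w)
    return g


def write_association_tsv(net: nx.Graph, path: str | Path) -> None:
    lines = []
    for a, b, attrs in sorted(net.edges(data=True)):
        lines.append(f"{a}\t{b}\t{attrs.get('weight', 1.0):.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
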