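"""Protein-protein interaction networks from STRING-style edge TSVs.

Graphs are simple undirected :class:`networkx.Graph` objects whose nodes are
gene symbols and whose ``weight`` edge attribute is an interaction confidence
in [0, 1].  STRING web exports print combined scores on a 0-1000 integer
scale; ``score_scale="auto"`` detects that dialect and rescales.

The confidence filter keeps edges with weight >= threshold (STRING's "high
confidence 0.700" cut is inclusive) and deliberately leaves the node set
untouched; dropping the resulting degree-0 nodes is a separate, explicit
step, mirroring the two independent choices made when exporting a filtered
network with disconnected nodes hidden.
"""

from __future__ import annotations

from pathlib import Path
from typing import Literal

import networkx as nx

from .errors import MalformedRowError, MissingColumnError, ValidationError

__all__ = [
    "read_edge_tsv",
    "filter_confidence",
    "drop_isolated",
    "graph_stats",
    "write_edge_tsv",
    "write_graphml",
    "write_sif",
]

ScoreScale = Literal["auto", "unit", "milli"]

#: column names recognized as node / score columns in STRING exports
_NODE_COLS = (("node1", "node2"), ("#node1", "node2"), ("protein1", "protein2"))
_SCORE_COLS = ("combined_score", "score", "weight")


def _add_edge(g: nx.Graph, a: str, b: str, w: float) -> None:
    if a == b:
        return  # self-loops carry no interaction information; dropped
    if g.has_edge(a, b):
        g[a][b]["weight"] = max(g[a][b]["weight"], w)
    else:
        g.add_edge(a, b, weight=w)


def read_edge_tsv(
    path: str | Path,
    score_scale: ScoreScale = "auto",
    node_columns: tuple[int, int] | None = None,
    score_column: int | None = None,
) -> nx.Graph:
    """Read a weighted edge list in the STRING-export TSV dialect.

    A header row is tolerated and used to locate the two node columns and the
    score column; headerless files default to columns (0, 1) for nodes and
    the last column for the score.  Column indices can be forced via
    ``node_columns`` / ``score_column``.

    ``score_scale``: "milli" divides scores by 1000; "unit" takes them as-is;
    "auto" picks "milli" iff any score exceeds 1.  Duplicate A-B / B-A rows
    collapse to one edge keeping the maximum weight; self-loops are dropped.
    """
    lines = Path(path).read_text(encoding="utf-8").splitlines()
    rows: list[tuple[int, str, str, str]] = []
    a_col, b_col = node_columns if node_columns else (0, 1)
    s_col = score_column
    start = 0
    if lines:
        header = [c.strip().lower() for c in lines[0].rstrip("\n").split("\t")]
        is_header = any(h in _SCORE_COLS for h in header) or any(
            header[:1] == [a] for a, _ in _NODE_COLS
        )
        if is_header:
            start = 1
            if node_columns is None:
                for a_name, b_name in _NODE_COLS:
                    if a_name in header and b_name in header:
                        a_col, b_col = header.index(a_name), header.index(b_name)
                        break
            if score_column is None:
                s_col = next(
                    (header.index(name) for name in _SCORE_COLS if name in header), None
                )
                if s_col is None:
                    raise MissingColumnError(
                        f"{path}: header has no score column (looked for {_SCORE_COLS})"
                    )
    for i, line in enumerate(lines[start:], start + 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) == 1:
            parts = line.split()
        sc = s_col if s_col is not None else len(parts) - 1
        if len(parts) < 3 or max(a_col, b_col, sc) >= len(parts):
            raise MalformedRowError(path, i, f"expected >=3 columns, got {len(parts)}")
        rows.append((i, parts[a_col].strip(), parts[b_col].strip(), parts[sc].strip()))

    scores: list[float] = []
    for i, _a, _b, s in rows:
        try:
            scores.append(float(s))
        except ValueError as exc:
            raise MalformedRowError(path, i, f"bad score {s!r}") from exc
    if score_scale == "auto":
        scale = "milli" if any(s > 1 for s in scores) else "unit"
    else:
        scale = score_scale

    g = nx.Graph()
    for (i, a, b, _s), s in zip(rows, scores):
        if not a or not b:
            raise MalformedRowError(path, i, "empty node name")
        w = s / 1000.0 if scale == "milli" else s
        if not 0.0 <= w <= 1.0:
            raise MalformedRowError(path, i, f"confidence {w} outside [0, 1]")
        _add_edge(g, a.upper(), b.upper(), w)
    return g


def filter_confidence(g: nx.Graph, threshold: float = 0.7) -> nx.Graph:
    """Keep edges with confidence >= threshold; the node set is unchanged."""
    if not 0.0 <= threshold <= 1.0:
        raise ValidationError(f"threshold must be in [0, 1], got {threshold}")
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    out.add_edges_from(
        (a, b, attrs) for a, b, attrs in g.edges(data=True)
        if attrs.get("weight", 1.0) >= threshold
    )
    return out


def drop_isolated(g: nx.Graph) -> nx.Graph:
    """Remove degree-0 nodes only."""
    out = g.copy()
    out.remove_nodes_from([v for v in g.nodes if g.degree(v) == 0])
    return out


def graph_stats(g: nx.Graph) -> tuple[int, int, int]:
    """Return (n_nodes, n_edges, n_components)."""
    return (
        g.number_of_nodes(),
        g.number_of_edges(),
        nx.number_connected_components(g) if g.number_of_nodes() else 0,
    )


def write_edge_tsv(g: nx.Graph, path: str | Path, header: bool = True) -> None:
    """Write the graph as a node1/node2/combined-score TSV (unit scale).

    Isolated nodes cannot be represented in an edge list and are not written.
    """
    lines = ["node1\tnode2\tcombined_score"] if header else []
    for a, b, attrs in sorted((tuple(sorted((a, b))) + (d,)) for a, b, d in g.edges(data=True)):
        lines.append(f"{a}\t{b}\t{attrs['weight']:.6g}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_graphml(g: nx.Graph, path: str | Path) -> None:
    nx.write_graphml(g, str(path))


def write_sif(g: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Cytoscape SIF: one '<a> <relation> <b>' line per edge; isolated nodes
    are written as bare names."""
    lines = [f"{a}\t{relation}\t{b}" for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges))]
    lines += [str(v) for v in sorted(g.nodes) if g.degree(v) == 0]
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")
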