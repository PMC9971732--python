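"""Drug-target-disease tripartite networks.

Nodes are typed (drug, disease, or target); edges record set membership only
and run exclusively between an entity (drug or disease) and a target.
Targets belonging to no entity set are kept as isolated nodes by default,
since an expanded related-target can legitimately be linked to neither a
drug nor a disease.  Exports: GraphML (kind attribute), SIF (relation
labels), and a Cytoscape-compatible elements JSON validated by a shipped
pydantic schema.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Literal, Mapping

import networkx as nx
from pydantic import BaseModel, ConfigDict

from .errors import ValidationError
from .targets import GeneSet

__all__ = [
    "build_network",
    "common_targets",
    "export",
    "load",
    "NODE_KINDS",
    "ElementsDocument",
]

NODE_KINDS = ("drug", "disease", "target")
_RELATIONS = {"drug": "targets", "disease": "associated_with"}


class _ElementData(BaseModel):
    model_config = ConfigDict(extra="forbid")
    id: str
    kind: Literal["drug", "disease", "target"]


class _EdgeData(BaseModel):
    model_config = ConfigDict(extra="forbid")
    source: str
    target: str
    interaction: Literal["targets", "associated_with"]


class _Node(BaseModel):
    data: _ElementData


class _Edge(BaseModel):
    data: _EdgeData


class _Elements(BaseModel):
    nodes: list[_Node]
    edges: list[_Edge]


class ElementsDocument(BaseModel):
    """Schema for the Cytoscape-style elements JSON export."""

    elements: _Elements


def build_network(
    drug_targets: Mapping[str, GeneSet],
    disease_targets: Mapping[str, GeneSet],
    all_targets: GeneSet,
    keep_isolated: bool = True,
) -> nx.Graph:
    """Assemble the tripartite network.

    Node count is #drugs + #diseases + |all_targets|; one edge per
    (entity, target) membership.  Entity sets containing genes outside
    ``all_targets`` are rejected with the offending genes listed.  Entity
    names colliding with target symbols (or one another) are rejected, since
    node identifiers must be unambiguous.
    """
    entities = list(drug_targets) + list(disease_targets)
    if len(set(entities)) != len(entities):
        raise ValidationError(f"duplicate entity names among {entities}")
    clash = set(entities) & all_targets.members
    if clash:
        raise ValidationError(f"entity names collide with target symbols: {sorted(clash)}")
    offenders = {}
    for name, gset in {**dict(drug_targets), **dict(disease_targets)}.items():
        extra = gset.members - all_targets.members
        if extra:
            offenders[name] = sorted(extra)
    if offenders:
        raise ValidationError(f"entity targets outside the target universe: {offenders}")

    g = nx.Graph()
    for name in drug_targets:
        g.add_node(name, kind="drug")
    for name in disease_targets:
        g.add_node(name, kind="disease")
    for t in all_targets.sorted():
        g.add_node(t, kind="target")
    for name, gset in drug_targets.items():
        g.add_edges_from((name, t) for t in gset.members)
    for name, gset in disease_targets.items():
        g.add_edges_from((name, t) for t in gset.members)
    if not keep_isolated:
        g.remove_nodes_from(
            [v for v, d in g.nodes(data=True) if d["kind"] == "target" and g.degree(v) == 0]
        )
    return g


def common_targets(
    drug_targets: Mapping[str, GeneSet], restrict_to: GeneSet
) -> GeneSet:
    """Targets shared by every drug, restricted to ``restrict_to``."""
    if len(drug_targets) < 2:
        raise ValidationError("common_targets needs at least 2 drugs")
    sets = [gs.members for gs in drug_targets.values()]
    common = frozenset.intersection(*sets) & restrict_to.members
    return GeneSet(
        "common_drug_targets",
        common,
        {g: frozenset(drug_targets) for g in common},
    )


def _to_elements(g: nx.Graph) -> dict:
    nodes = [
        {"data": {"id": v, "kind": g.nodes[v]["kind"]}} for v in sorted(g.nodes)
    ]
    edges = []
    for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
        ka, kb = g.nodes[a]["kind"], g.nodes[b]["kind"]
        # orient entity -> target
        src, dst = (a, b) if ka in _RELATIONS else (b, a)
        edges.append(
            {
                "data": {
                    "source": src,
                    "target": dst,
                    "interaction": _RELATIONS[g.nodes[src]["kind"]],
                }
            }
        )
    return {"elements": {"nodes": nodes, "edges": edges}}


def export(g: nx.Graph, path: str | Path, format: Literal["graphml", "sif", "json"]) -> None:
    """Write the network; graphml/json round-trip exactly, sif is edge-complete."""
    path = Path(path)
    if format == "graphml":
        nx.write_graphml(g, str(path))
    elif format == "sif":
        lines = []
        for a, b in sorted(map(lambda e: tuple(sorted(e)), g.edges)):
            src, dst = (a, b) if g.nodes[a]["kind"] in _RELATIONS else (b, a)
            lines.append(f"{src}\t{_RELATIONS[g.nodes[src]['kind']]}\t{dst}")
        lines += [v for v in sorted(g.nodes) if g.degree(v) == 0]
        path.write_text("\n".join(lines) + "\n", encoding="utf-8")
    elif format == "json":
        doc = _to_elements(g)
        ElementsDocument.model_validate(doc)  # shipped schema check
        path.write_text(json.dumps(doc, indent=1, sort_keys=True), encoding="utf-8")
    else:
        raise ValidationError(f"unknown export format {format!r}")


def load(path: str | Path, format: Literal["graphml", "json"]) -> nx.Graph:
    """Re-import a graphml or elements-JSON export."""
    path = Path(path)
    if format == "graphml":
        return nx.read_graphml(str(path))
    if format == "json":
        doc = ElementsDocument.model_validate_json(path.read_text(encoding="utf-8"))
        g = nx.Graph()
        for node in doc.elements.nodes:
            g.add_node(node.data.id, kind=node.data.kind)
        for edge in doc.elements.edges:
            g.add_edge(edge.data.source, edge.data.target)
        return g
    raise ValidationError(f"unknown import format {format!r}")
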