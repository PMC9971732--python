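"""Hub-gene centralities and the consensus core-target rule.

Four local-topology centralities are computed on the (unweighted view of
the) filtered PPI network:

* **degree** - number of neighbors.
* **MNC** (maximum neighborhood component) - size of the largest connected
  component of the open neighborhood N(v).
* **MCC** (maximal clique centrality) - sum over all maximal cliques C
  containing v of (|C| - 1)!, kept in exact integer arithmetic because the
  factorials explode quickly.
* **EPC** (edge percolated component) - expected size of v's connected
  component when every edge is independently retained with probability
  ``retention_p``, estimated by seeded Monte-Carlo over ``replicates``
  percolated graphs.

A node is a *core target* (hub) when its value is strictly above the
per-algorithm arithmetic mean, simultaneously for all four algorithms.
Means are taken over all nodes of the analyzed graph.  Edge weights are
ignored by all four centralities: the confidence filter has already been
applied, and the filtered network is treated as unweighted.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction
from math import factorial

import networkx as nx
import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.sparse.csgraph import connected_components

from .errors import CliqueLimitExceededError, EmptyGraphError, ValidationError
from .targets import GeneSet

__all__ = [
    "EPCParams",
    "HubResult",
    "degree",
    "mnc",
    "mcc",
    "epc",
    "centrality_table",
    "consensus_hubs",
]

#: abort MCC if a graph yields more maximal cliques than this
DEFAULT_CLIQUE_CAP = 10**6


@dataclass(frozen=True)
class EPCParams:
    """Monte-Carlo parameters for the edge-percolated-component centrality.

    ``retention_p`` is the independent per-edge retention probability and
    ``replicates`` the number of percolated graphs averaged over; both follow
    the conventional reference values (0.5, 1000).  The seed makes the
    estimate reproducible.
    """

    replicates: int = 1000
    retention_p: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if self.replicates < 1:
            raise ValidationError("EPC replicates must be >= 1")
        if not 0.0 <= self.retention_p <= 1.0:
            raise ValidationError("EPC retention_p must be in [0, 1]")


@dataclass(frozen=True)
class HubResult:
    hubs: GeneSet
    table: pd.DataFrame
    means: dict


def degree(g: nx.Graph) -> dict[str, int]:
    return {v: int(d) for v, d in g.degree()}


def mnc(g: nx.Graph) -> dict[str, int]:
    """Size of the largest connected component of each node's open
    neighborhood (0 for isolated nodes)."""
    out = {}
    for v in g.nodes:
        nbrs = list(g.neighbors(v))
        if not nbrs:
            out[v] = 0
            continue
        sub = g.subgraph(nbrs)
        out[v] = max(len(c) for c in nx.connected_components(sub))
    return out


def mcc(g: nx.Graph, clique_cap: int = DEFAULT_CLIQUE_CAP) -> dict[str, int]:
    """Maximal clique centrality with exact big-integer factorials.

    Maximal cliques are enumerated once for the whole graph (Bron-Kerbosch
    with pivoting); enumeration aborts with
    :class:`~netpharm.errors.CliqueLimitExceededError` after ``clique_cap``
    cliques on pathological graphs.  An isolated node lies in the maximal
    clique {v} of size 1, contributing 0! = 1; it is reported as 0 to keep
    the conventional "no interactions, no centrality" reading.
    """
    out: dict[str, int] = {v: 0 for v in g.nodes}
    for n_seen, clique in enumerate(nx.find_cliques(g), 1):
        if n_seen > clique_cap:
            raise CliqueLimitExceededError(
                f"more than {clique_cap} maximal cliques; raise clique_cap to proceed"
            )
        if len(clique) == 1:
            continue
        contrib = factorial(len(clique) - 1)
        for v in clique:
            out[v] += contrib
    return out


def epc(g: nx.Graph, params: EPCParams | None = None) -> dict[str, float]:
    """Monte-Carlo edge-percolated component centrality.

    For each replicate, every edge is kept independently with probability
    ``retention_p``; EPC(v) is the mean size of v's connected component
    (counting v itself).  Deterministic for a fixed seed.
    """
    params = params or EPCParams()
    nodes = list(g.nodes)
    n = len(nodes)
    if n == 0:
        return {}
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(idx[a], idx[b]) for a, b in g.edges], dtype=np.int64).reshape(-1, 2)
    m = len(edges)
    rng = np.random.default_rng(params.seed)
    totals = np.zeros(n, dtype=np.float64)
    for _ in range(params.replicates):
        if m and params.retention_p > 0.0:
            keep = rng.random(m) < params.retention_p
            kept = edges[keep]
        else:
            kept = edges[:0]
        if len(kept):
            adj = sp.coo_matrix(
                (np.ones(len(kept)), (kept[:, 0], kept[:, 1])), shape=(n, n)
            )
            _, labels = connected_components(adj, directed=False)
            sizes = np.bincount(labels, minlength=labels.max() + 1)
            totals += sizes[labels]
        else:
            totals += 1.0
    vals = totals / params.replicates
    return {v: float(vals[idx[v]]) for v in nodes}


def centrality_table(
    g: nx.Graph,
    epc_params: EPCParams | None = None,
    clique_cap: int = DEFAULT_CLIQUE_CAP,
) -> tuple[pd.DataFrame, dict]:
    """Per-node table of the four centralities with per-algorithm means and
    strict above-the-mean pass flags.

    Pass flags for the integer-valued algorithms are decided in exact
    arithmetic (value * n > column sum), so ties at the mean never pass due
    to floating-point noise.
    """
    if g.number_of_nodes() == 0:
        raise EmptyGraphError("centrality analysis needs a non-empty graph")
    deg = degree(g)
    mnc_v = mnc(g)
    mcc_v = mcc(g, clique_cap=clique_cap)
    epc_v = epc(g, epc_params)
    nodes = sorted(g.nodes)
    n = len(nodes)
    sums = {
        "degree": sum(deg.values()),
        "mnc": sum(mnc_v.values()),
        "mcc": sum(mcc_v.values()),
    }
    epc_mean = float(np.mean([epc_v[v] for v in nodes]))
    means = {
        "degree": sums["degree"] / n,
        "mnc": sums["mnc"] / n,
        "mcc": float(Fraction(sums["mcc"], n)),
        "epc": epc_mean,
    }
    rows = []
    for v in nodes:
        rows.append(
            {
                "node": v,
                "degree": deg[v],
                "mnc": mnc_v[v],
                "mcc": mcc_v[v],
                "epc": epc_v[v],
                "pass_degree": deg[v] * n > sums["degree"],
                "pass_mnc": mnc_v[v] * n > sums["mnc"],
                "pass_mcc": mcc_v[v] * n > sums["mcc"],
                "pass_epc": epc_v[v] > epc_mean,
            }
        )
    table = pd.DataFrame(rows).set_index("node")
    return table, means


def consensus_hubs(
    g: nx.Graph,
    epc_params: EPCParams | None = None,
    clique_cap: int = DEFAULT_CLIQUE_CAP,
) -> HubResult:
    """Core targets: nodes strictly above the mean of all four centralities."""
    table, means = centrality_table(g, epc_params, clique_cap)
    mask = (
        table["pass_degree"] & table["pass_mnc"] & table["pass_mcc"] & table["pass_epc"]
    )
    hub_nodes = frozenset(table.index[mask])
    hubs = GeneSet(
        "core_targets", hub_nodes, {v: frozenset({"consensus_centrality"}) for v in hub_nodes}
    )
    return HubResult(hubs=hubs, table=table, means=means)
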