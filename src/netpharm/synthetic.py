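"""Synthetic fixtures with recorded ground truth.

No public accessions back the original database exports, so every pipeline
stage is exercised against generated data whose planted structure is known
exactly:

* target universes of synthetic symbols (``G000001``...),
* per-entity target sets realized from *exact* Venn-region counts
  (constructive assignment, not sampling, so region tests are sharp),
* weighted association networks with planted strongly-linked associates,
* PPI graphs with planted cliques (modules), planted multi-clique hubs,
  designated post-filter isolates, and a sparse background engineered so
  that the high-confidence subgraph of the background contains no 2-core
  (planted-module recovery is then structural, not statistical),
* gene-set / regulon libraries with planted enriched terms.

All sampling is integer-indexed over sorted sequences through a seeded
``numpy`` generator, so fixtures are bit-identical across platforms.
``validate_truth`` re-checks every ground-truth claim against the generated
artifacts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import numpy as np

from .errors import UnsatisfiableSpecError, ValidationError
from .targets import GeneSet
from .enrich import GeneSetLibrary

__all__ = [
    "FixtureTruth",
    "TargetSetSpec",
    "StudyFixture",
    "gen_universe",
    "gen_target_sets",
    "gen_ppi",
    "gen_association",
    "gen_library",
    "gen_study",
    "validate_truth",
]

HIGH_CONF = 0.7  # weights at or above this survive the confidence filter


@dataclass
class FixtureTruth:
    """Ground truth recorded alongside every generated artifact."""

    seed: int
    planted_intersection: frozenset[str] = frozenset()
    planted_associates: frozenset[str] = frozenset()
    planted_hubs: frozenset[str] = frozenset()
    planted_modules: list[frozenset[str]] = field(default_factory=list)
    enriched_terms: list[str] = field(default_factory=list)
    common_core: frozenset[str] = frozenset()
    extras: dict = field(default_factory=dict)

    def to_json(self) -> dict:
        return {
            "seed": self.seed,
            "planted_intersection": sorted(self.planted_intersection),
            "planted_associates": sorted(self.planted_associates),
            "planted_hubs": sorted(self.planted_hubs),
            "planted_modules": [sorted(m) for m in self.planted_modules],
            "enriched_terms": list(self.enriched_terms),
            "common_core": sorted(self.common_core),
            "extras": self.extras,
        }


def gen_universe(n: int, seed: int = 0) -> list[str]:
    """``n`` unique synthetic symbols G000001..G{n}, identical for any seed."""
    if n < 1:
        raise ValidationError(f"universe size must be >= 1, got {n}")
    del seed  # symbol content is seed-independent by design; kept for API symmetry
    return [f"G{i:06d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# target sets from exact region counts

@dataclass(frozen=True)
class TargetSetSpec:
    """Exact Venn-region counts over a collection of named entities.

    ``region_counts`` maps a frozenset of entity names (the sets that contain
    the region, and no others) to the number of genes in that region.  Entity
    sizes, overlaps, nesting and common cores are all expressible this way.
    """

    region_counts: Mapping[frozenset, int]

    @property
    def entities(self) -> tuple[str, ...]:
        names: set[str] = set()
        for sig in self.region_counts:
            names |= set(sig)
        return tuple(sorted(names))

    def size_of(self, entity: str) -> int:
        return sum(c for sig, c in self.region_counts.items() if entity in sig)

    @classmethod
    def with_common_core(cls, sizes: Mapping[str, int], core: int) -> "TargetSetSpec":
        """Entities of the given sizes sharing exactly ``core`` genes, with no
        other overlap."""
        names = sorted(sizes)
        for n, s in sizes.items():
            if s < core:
                raise UnsatisfiableSpecError(
                    f"entity {n!r} size {s} smaller than the common core {core}"
                )
        counts: dict[frozenset, int] = {frozenset(names): core}
        for n in names:
            only = sizes[n] - core
            if only:
                counts[frozenset({n})] = only
        return cls(counts)

    @classmethod
    def nested(cls, inner: str, outer: str, inner_size: int, outer_size: int) -> "TargetSetSpec":
        if inner_size > outer_size:
            raise UnsatisfiableSpecError(
                f"nested spec needs |{inner}| <= |{outer}|"
            )
        counts: dict[frozenset, int] = {frozenset({inner, outer}): inner_size}
        if outer_size > inner_size:
            counts[frozenset({outer})] = outer_size - inner_size
        return cls(counts)


def gen_target_sets(
    universe: Sequence[str],
    spec: TargetSetSpec,
    seed: int = 0,
) -> tuple[dict[str, GeneSet], FixtureTruth]:
    """Realize entity gene sets whose Venn regions match ``spec`` exactly.

    Genes are drawn without replacement from the universe in a seeded
    permutation and assigned region by region (regions sorted for
    determinism).  Raises
    :class:`~netpharm.errors.UnsatisfiableSpecError` when the universe is too
    small or a count is negative / keyed by an empty signature.
    """
    total = 0
    for sig, c in spec.region_counts.items():
        if not sig:
            raise UnsatisfiableSpecError("region signature must name at least one entity")
        if c < 0:
            raise UnsatisfiableSpecError(f"negative region count for {sorted(sig)}")
        total += c
    if total > len(universe):
        raise UnsatisfiableSpecError(
            f"regions need {total} genes but the universe has {len(universe)}"
        )
    rng = np.random.default_rng(seed)
    pool = [universe[i] for i in rng.permutation(len(universe))]
    cursor = 0
    assignment: dict[frozenset, list[str]] = {}
    for sig in sorted(spec.region_counts, key=lambda s: (len(s), tuple(sorted(s)))):
        c = spec.region_counts[sig]
        assignment[sig] = pool[cursor : cursor + c]
        cursor += c
    sets: dict[str, GeneSet] = {}
    for name in spec.entities:
        members = frozenset(
            g for sig, genes in assignment.items() if name in sig for g in genes
        )
        sets[name] = GeneSet(name, members, {g: frozenset({"synthetic"}) for g in members})
    truth = FixtureTruth(
        seed=seed,
        extras={
            "regions": {
                "|".join(sorted(sig)): sorted(genes) for sig, genes in assignment.items()
            }
        },
    )
    return sets, truth


# ---------------------------------------------------------------------------
# PPI graphs with planted structure

def gen_ppi(
    n_background: int,
    planted_modules: Sequence[int] = (),
    planted_hubs: int = 0,
    background_p: float = 0.05,
    seed: int = 0,
    node_names: Sequence[str] | None = None,
    n_isolates: int = 0,
) -> tuple[nx.Graph, FixtureTruth]:
    """PPI graph with planted cliques, hubs, and an engineered sparse background.

    Planted cliques are fully wired at high confidence (weights in
    [0.7, 1.0]) and joined to the rest of the graph by a single
    high-confidence bridge each.  Hub nodes attach to every member of three
    planted cliques (requiring >= 3 cliques when hubs are planted).
    Non-isolate background nodes sit on a random high-confidence spanning
    tree plus Erdos-Renyi extra edges at ``background_p`` with weights in
    [0.4, 1.0]; any extra edge that would leave a 2-core in the
    high-confidence background subgraph is demoted below 0.7, so
    planted-module recovery after filtering is exact by construction.
    Designated isolates receive only sub-threshold edges and drop out of the
    filtered network.
    """
    if n_isolates > n_background:
        raise UnsatisfiableSpecError("more isolates than background nodes")
    if planted_hubs > 0 and len(planted_modules) < 3:
        raise UnsatisfiableSpecError("planted hubs require >= 3 planted cliques")
    if any(s < 2 for s in planted_modules):
        raise UnsatisfiableSpecError("planted clique sizes must be >= 2")
    if not 0.0 <= background_p <= 1.0:
        raise ValidationError("background_p must be in [0, 1]")
    total = sum(planted_modules) + planted_hubs + n_background
    rng = np.random.default_rng(seed)
    if node_names is None:
        names = [f"P{i:04d}" for i in range(1, total + 1)]
    else:
        if len(node_names) != total:
            raise UnsatisfiableSpecError(
                f"{len(node_names)} node names given but the layout needs {total}"
            )
        names = list(node_names)
    names = [names[i] for i in rng.permutation(len(names))]

    cursor = 0
    modules: list[list[str]] = []
    for size in planted_modules:
        modules.append(names[cursor : cursor + size])
        cursor += size
    hubs = names[cursor : cursor + planted_hubs]
    cursor += planted_hubs
    background = names[cursor:]
    isolates = background[len(background) - n_isolates :] if n_isolates else []
    linked_bg = background[: len(background) - n_isolates]

    g = nx.Graph()
    g.add_nodes_from(names)

    def w_high() -> float:
        return float(rng.uniform(HIGH_CONF, 1.0))

    def w_any() -> float:
        return float(rng.uniform(0.4, 1.0))

    def w_low() -> float:
        return float(rng.uniform(0.4, HIGH_CONF - 0.001))

    for mod in modules:
        for i in range(len(mod)):
            for j in range(i + 1, len(mod)):
                g.add_edge(mod[i], mod[j], weight=w_high())
    for h in hubs:
        by_size = sorted(range(len(modules)), key=lambda i: (-len(modules[i]), i))
        for mi in by_size[:3]:
            for v in modules[mi]:
                g.add_edge(h, v, weight=w_high())

    # high-confidence spanning tree over the linked background
    for i in range(1, len(linked_bg)):
        j = int(rng.integers(0, i))
        g.add_edge(linked_bg[i], linked_bg[j], weight=w_high())
    # ER extras among the linked background
    tree_edges = {frozenset(e) for e in g.edges if set(e) <= set(linked_bg)}
    extras: list[frozenset] = []
    for i in range(len(linked_bg)):
        for j in range(i + 1, len(linked_bg)):
            pair = frozenset({linked_bg[i], linked_bg[j]})
            if pair in tree_edges:
                continue
            if rng.random() < background_p:
                g.add_edge(linked_bg[i], linked_bg[j], weight=w_any())
                extras.append(pair)
    # one bridge per clique into the linked background
    for mod in modules:
        if linked_bg:
            a = mod[int(rng.integers(0, len(mod)))]
            b = linked_bg[int(rng.integers(0, len(linked_bg)))]
            if not g.has_edge(a, b):
                g.add_edge(a, b, weight=w_high())
    # isolates: only sub-threshold edges
    for v in isolates:
        if linked_bg:
            b = linked_bg[int(rng.integers(0, len(linked_bg)))]
            g.add_edge(v, b, weight=w_low())

    # demote extras until the high-confidence background subgraph is 2-core-free
    extra_set = set(extras)
    while True:
        hi = nx.Graph()
        hi.add_nodes_from(linked_bg)
        hi.add_edges_from(
            (a, b)
            for a, b, d in g.edges(data=True)
            if a in hi and b in hi and d["weight"] >= HIGH_CONF
        )
        core = nx.k_core(hi, 2)
        if core.number_of_nodes() == 0:
            break
        victim = min(
            tuple(sorted(e)) for e in core.edges if frozenset(e) in extra_set
        )
        a, b = victim
        g[a][b]["weight"] = w_low()

    truth = FixtureTruth(
        seed=seed,
        planted_hubs=frozenset(hubs),
        planted_modules=[frozenset(m) for m in modules],
        extras={
            "isolates": sorted(isolates),
            "background": sorted(background),
            "n_nodes": total,
        },
    )
    return g, truth


# ---------------------------------------------------------------------------
# association networks

def gen_association(
    seeds: Iterable[str],
    n_associates: int,
    background: Iterable[str],
    seed: int = 0,
    associate_names: Sequence[str] | None = None,
    links_per_associate: int = 3,
) -> tuple[nx.Graph, FixtureTruth]:
    """Functional-association network with planted associates.

    Each planted associate links to ``links_per_associate`` distinct seeds at
    high association strength (>= 0.7); background genes link to at most one
    seed, weakly (< 0.7).  The degree-normalized connectivity score of any
    associate therefore exceeds every background score deterministically
    (3 * 0.7 / sqrt(3) > 0.7), making top-k recovery exact.
    """
    seed_list = sorted(set(seeds))
    bg_list = sorted(set(background))
    if links_per_associate < 1 or links_per_associate > len(seed_list):
        raise UnsatisfiableSpecError(
            f"links_per_associate must be in [1, {len(seed_list)}]"
        )
    rng = np.random.default_rng(seed)
    if associate_names is None:
        associates = [f"A{i:04d}" for i in range(1, n_associates + 1)]
    else:
        if len(associate_names) != n_associates:
            raise UnsatisfiableSpecError("associate_names length != n_associates")
        associates = list(associate_names)
    overlap = (set(associates) | set(bg_list)) & set(seed_list)
    if overlap:
        raise UnsatisfiableSpecError(
            f"associates/background overlap the seed set: {sorted(overlap)[:5]}"
        )

    g = nx.Graph()
    g.add_nodes_from(seed_list)
    for a in associates:
        picks = rng.choice(len(seed_list), size=links_per_associate, replace=False)
        for i in picks:
            g.add_edge(a, seed_list[int(i)], weight=float(rng.uniform(HIGH_CONF, 1.0)))
    for b in bg_list:
        if rng.random() < 0.6:
            i = int(rng.integers(0, len(seed_list)))
            g.add_edge(b, seed_list[i], weight=float(rng.uniform(0.3, HIGH_CONF - 0.001)))
        else:
            g.add_node(b)
    # a little seed-seed structure (does not affect candidate scores)
    for i in range(len(seed_list) - 1):
        if rng.random() < 0.3:
            g.add_edge(
                seed_list[i], seed_list[i + 1], weight=float(rng.uniform(0.3, 1.0))
            )
    truth = FixtureTruth(seed=seed, planted_associates=frozenset(associates))
    return g, truth


# ---------------------------------------------------------------------------
# gene-set libraries

def gen_library(
    universe: Sequence[str],
    n_terms: int,
    term_size_range: tuple[int, int],
    planted: Sequence[tuple[str, Iterable[str]]] = (),
    seed: int = 0,
    name: str = "synthetic_library",
    pad_planted_to: int | None = None,
) -> tuple[GeneSetLibrary, FixtureTruth]:
    """Random gene-set library plus planted enriched terms.

    Random terms draw their genes uniformly (without replacement) from the
    universe with sizes uniform over ``term_size_range``.  Each planted term
    contains exactly the genes supplied (its enrichment signal), optionally
    padded with random other universe genes up to ``pad_planted_to``.
    """
    lo, hi = term_size_range
    if lo < 1 or hi < lo:
        raise UnsatisfiableSpecError(f"bad term_size_range {term_size_range}")
    if hi > len(universe):
        raise UnsatisfiableSpecError("term sizes exceed the universe")
    rng = np.random.default_rng(seed)
    uni = sorted(universe)
    terms: dict[str, frozenset[str]] = {}
    for t in range(1, n_terms + 1):
        size = int(rng.integers(lo, hi + 1))
        picks = rng.choice(len(uni), size=size, replace=False)
        terms[f"{name.upper()}_TERM_{t:04d}"] = frozenset(uni[int(i)] for i in picks)
    planted_names = []
    for term_name, genes in planted:
        gs = set(genes)
        missing = gs - set(uni)
        if missing:
            raise UnsatisfiableSpecError(
                f"planted genes outside the universe: {sorted(missing)[:5]}"
            )
        if pad_planted_to is not None and pad_planted_to > len(gs):
            others = [g for g in uni if g not in gs]
            picks = rng.choice(len(others), size=pad_planted_to - len(gs), replace=False)
            gs |= {others[int(i)] for i in picks}
        terms[term_name] = frozenset(gs)
        planted_names.append(term_name)
    lib = GeneSetLibrary(name, terms, frozenset(uni))
    truth = FixtureTruth(seed=seed, enriched_terms=planted_names)
    return lib, truth


# ---------------------------------------------------------------------------
# the full demo study

@dataclass
class StudyFixture:
    """Everything the pipeline consumes for one synthetic study, plus truth."""

    universe: list[str]
    drug_sources: dict[str, dict[str, list[str]]]
    disease_sources: dict[str, dict[str, list[str]]]
    drugs: dict[str, GeneSet]
    diseases: dict[str, GeneSet]
    assoc_net: nx.Graph
    ppi_graph: nx.Graph
    pathway_library: GeneSetLibrary
    tf_library: GeneSetLibrary
    truth: FixtureTruth


#: Venn-region layout of the demo study; mirrors the nested-disease /
#: 31-gene intersection / 12-gene common-core structure of the motivating
#: analysis, with drug-only and disease-only bulk sized to the same order.
_STUDY_REGIONS = {
    ("albiglutide", "liraglutide", "semaglutide", "T2DM", "MI"): 12,
    ("albiglutide", "T2DM", "MI"): 7,
    ("liraglutide", "T2DM", "MI"): 6,
    ("semaglutide", "T2DM", "MI"): 6,
    ("albiglutide", "T2DM"): 5,
    ("liraglutide", "T2DM"): 5,
    ("semaglutide", "T2DM"): 5,
    ("albiglutide", "liraglutide"): 10,
    ("albiglutide", "semaglutide"): 8,
    ("liraglutide", "semaglutide"): 7,
    ("albiglutide",): 50,
    ("liraglutide",): 45,
    ("semaglutide",): 32,
    ("T2DM", "MI"): 480,
    ("T2DM",): 4097,
}

DRUG_NAMES = ("albiglutide", "liraglutide", "semaglutide")
DISEASE_NAMES = ("T2DM", "MI")
DRUG_SOURCE_NAMES = ("bindingdb", "sea", "swisstarget", "targetnet")
DISEASE_SOURCE_NAMES = ("genecards", "omim", "pharmgkb", "ttd", "drugbank")


def _split_sources(
    members: Sequence[str], source_names: Sequence[str], rng: np.random.Generator
) -> dict[str, list[str]]:
    """Assign every gene to >= 1 source so the aggregated union is exact."""
    out: dict[str, list[str]] = {s: [] for s in source_names}
    k = len(source_names)
    for g in sorted(members):
        n_src = 1 + int(rng.binomial(k - 1, 0.25))
        picks = rng.choice(k, size=n_src, replace=False)
        for i in picks:
            out[source_names[int(i)]].append(g)
    return out


def gen_study(seed: int = 0) -> StudyFixture:
    """Generate the complete synthetic study the demo pipeline runs on.

    The layout plants: a 31-gene drug/disease intersection containing a
    12-gene all-drug core, nested disease sets (MI analog inside the T2DM
    analog), 20 strongly-linked associates, a PPI over the 51 related genes
    with three cliques (6/5/4), five hubs and five designated isolates, a
    200-term pathway library with one planted term per module, and a 50-TF
    regulon library whose planted regulon covers every planted hub and
    module gene.
    """
    universe = gen_universe(6000, seed)
    spec = TargetSetSpec({frozenset(k): v for k, v in _STUDY_REGIONS.items()})
    sets, set_truth = gen_target_sets(universe, spec, seed)
    drugs = {n: sets[n] for n in DRUG_NAMES}
    diseases = {n: sets[n] for n in DISEASE_NAMES}
    regions = set_truth.extras["regions"]
    intersection = frozenset(
        g
        for key, genes in regions.items()
        if set(DISEASE_NAMES) <= set(key.split("|"))
        and set(key.split("|")) & set(DRUG_NAMES)
        for g in genes
    )
    core = frozenset(regions["|".join(sorted(DRUG_NAMES + DISEASE_NAMES))])

    rng = np.random.default_rng([seed, 1])
    drug_sources = {
        d: _split_sources(sorted(drugs[d].members), DRUG_SOURCE_NAMES, rng)
        for d in DRUG_NAMES
    }
    disease_sources = {
        d: _split_sources(sorted(diseases[d].members), DISEASE_SOURCE_NAMES, rng)
        for d in DISEASE_NAMES
    }

    used = frozenset().union(*(s.members for s in sets.values()))
    free = [g for g in universe if g not in used]
    t2dm_only = regions["T2DM"]
    picks = rng.choice(len(t2dm_only), 166, replace=False)
    # 16 associates are disease genes, 4 are novel: expanded targets mostly
    # reconnect to the diseases in the tripartite network, a few to nothing
    associates = [t2dm_only[int(i)] for i in picks[:16]] + free[:4]
    assoc_bg = [t2dm_only[int(i)] for i in picks[16:]]
    assoc_net, assoc_truth = gen_association(
        seeds=intersection,
        n_associates=20,
        background=assoc_bg,
        seed=seed,
        associate_names=associates,
    )
    related = sorted(intersection | frozenset(associates))

    ppi_graph, ppi_truth = gen_ppi(
        n_background=len(related) - (6 + 5 + 4) - 5,
        planted_modules=(6, 5, 4),
        planted_hubs=5,
        background_p=0.05,
        seed=seed,
        node_names=related,
        n_isolates=5,
    )

    lib_universe = sorted(
        set(related)
        | {universe[int(i)] for i in rng.choice(len(universe), 2200, replace=False)}
    )[:2000]
    lib_universe = sorted(set(lib_universe) | set(related))
    planted_terms = [
        (f"PW_PLANTED_M{i + 1}", sorted(mod))
        for i, mod in enumerate(ppi_truth.planted_modules)
    ]
    pathway_library, _ = gen_library(
        lib_universe,
        n_terms=200,
        term_size_range=(5, 50),
        planted=planted_terms,
        seed=seed,
        name="pathways",
        pad_planted_to=20,
    )

    tf_universe = sorted(
        set(related)
        | {universe[int(i)] for i in rng.choice(len(universe), 600, replace=False)}
    )[:500]
    tf_universe = sorted(set(tf_universe) | set(related))
    regulon = sorted(
        ppi_truth.planted_hubs | frozenset().union(*ppi_truth.planted_modules)
    )
    tf_library, _ = gen_library(
        tf_universe,
        n_terms=50,
        term_size_range=(10, 40),
        planted=[("TF_PLANTED", regulon)],
        seed=seed,
        name="regulons",
        pad_planted_to=30,
    )

    truth = FixtureTruth(
        seed=seed,
        planted_intersection=intersection,
        planted_associates=frozenset(associates),
        planted_hubs=ppi_truth.planted_hubs,
        planted_modules=ppi_truth.planted_modules,
        enriched_terms=[t for t, _ in planted_terms] + ["TF_PLANTED"],
        common_core=core,
        extras={
            "related": related,
            "ppi_isolates": ppi_truth.extras["isolates"],
            "regions": {k: len(v) for k, v in regions.items()},
        },
    )
    return StudyFixture(
        universe=universe,
        drug_sources=drug_sources,
        disease_sources=disease_sources,
        drugs=drugs,
        diseases=diseases,
        assoc_net=assoc_net,
        ppi_graph=ppi_graph,
        pathway_library=pathway_library,
        tf_library=tf_library,
        truth=truth,
    )


def validate_truth(fix: StudyFixture) -> list[str]:
    """Re-check every ground-truth claim against the generated artifacts.

    Returns a list of human-readable findings; an empty list means every
    claim holds.
    """
    findings: list[str] = []
    t = fix.truth
    drug_union = frozenset().union(*(s.members for s in fix.drugs.values()))
    actual_inter = drug_union
    for s in fix.diseases.values():
        actual_inter = actual_inter & s.members
    if actual_inter != t.planted_intersection:
        findings.append("planted intersection != realized drug/disease intersection")
    inner, outer = fix.diseases["MI"].members, fix.diseases["T2DM"].members
    if not inner <= outer:
        findings.append("disease nesting violated (MI analog not inside T2DM analog)")
    for d, gset in fix.drugs.items():
        if not t.common_core <= gset.members:
            findings.append(f"common core missing from drug {d}")
        agg = set().union(*fix.drug_sources[d].values())
        if agg != set(gset.members):
            findings.append(f"per-source split of {d} does not union to its target set")
    for a in t.planted_associates:
        links = [
            s for s in fix.assoc_net[a]
            if s in t.planted_intersection and fix.assoc_net[a][s]["weight"] >= HIGH_CONF
        ] if fix.assoc_net.has_node(a) else []
        if len(links) < 3:
            findings.append(f"associate {a} lacks 3 strong seed links")
    for i, mod in enumerate(t.planted_modules):
        for a in mod:
            for b in mod:
                if a < b and (
                    not fix.ppi_graph.has_edge(a, b)
                    or fix.ppi_graph[a][b]["weight"] < HIGH_CONF
                ):
                    findings.append(f"module {i + 1} is not a high-confidence clique")
    for h in t.planted_hubs:
        attached = sum(
            1
            for mod in t.planted_modules
            if all(
                fix.ppi_graph.has_edge(h, v)
                and fix.ppi_graph[h][v]["weight"] >= HIGH_CONF
                for v in mod
            )
        )
        if attached < 3:
            findings.append(f"hub {h} not attached to 3 planted cliques")
    for v in t.extras["ppi_isolates"]:
        if any(d["weight"] >= HIGH_CONF for _, _, d in fix.ppi_graph.edges(v, data=True)):
            findings.append(f"designated isolate {v} has a high-confidence edge")
    for term in t.enriched_terms:
        lib = fix.tf_library if term.startswith("TF_") else fix.pathway_library
        if term not in lib.terms:
            findings.append(f"planted term {term} missing from its library")
    if not t.common_core <= t.planted_intersection:
        findings.append("common core not inside the planted intersection")
    return findings


# ---------------------------------------------------------------------------
# writing fixtures to disk in the formats the pipeline reads

def write_study(fix: StudyFixture, outdir: str | Path) -> dict[str, object]:
    """Persist a study fixture (gene lists, TSVs, GMTs, truth JSON).

    Returns a manifest of relative paths suitable for building a pipeline
    configuration.
    """
    import json

    from .assoc import write_association_tsv
    from .enrich import write_gmt
    from .ppi import write_edge_tsv

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, object] = {"drug_sources": {}, "disease_sources": {}}
    for d, sources in fix.drug_sources.items():
        manifest["drug_sources"][d] = {}
        for s, genes in sources.items():
            rel = f"targets/drug_{d}_{s}.txt"
            p = out / rel
            p.parent.mkdir(parents=True, exist_ok=True)
            p.write_text("\n".join(genes) + "\n", encoding="utf-8")
            manifest["drug_sources"][d][s] = rel
    for d, sources in fix.disease_sources.items():
        manifest["disease_sources"][d] = {}
        for s, genes in sources.items():
            rel = f"targets/disease_{d}_{s}.txt"
            (out / rel).write_text("\n".join(genes) + "\n", encoding="utf-8")
            manifest["disease_sources"][d][s] = rel
    write_association_tsv(fix.assoc_net, out / "association.tsv")
    manifest["association_network"] = "association.tsv"
    write_edge_tsv(fix.ppi_graph, out / "ppi.tsv")
    manifest["ppi_network"] = "ppi.tsv"
    write_gmt(fix.pathway_library, out / "pathways.gmt")
    manifest["libraries"] = {"pathways": "pathways.gmt"}
    write_gmt(fix.tf_library, out / "regulons.gmt")
    manifest["tf_library"] = "regulons.gmt"
    (out / "truth.json").write_text(
        json.dumps(fix.truth.to_json(), indent=1, sort_keys=True), encoding="utf-8"
    )
    manifest["truth"] = "truth.json"
    return manifest
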