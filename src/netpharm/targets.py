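"""Gene-symbol normalization and target-set algebra.

Drug and disease targets arrive as plain lists of gene symbols exported from
heterogeneous databases.  This module normalizes them into :class:`GeneSet`
objects (uppercase HGNC-style symbols with per-gene source provenance) and
provides the set operations the analysis is built from: per-source
aggregation, Venn-region decomposition, related-set union, and containment
reports.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import LabelClashError, SymbolError, ValidationError

__all__ = [
    "GeneSet",
    "VennResult",
    "normalize_symbols",
    "aggregate_sources",
    "venn",
    "combine_related",
    "containment_report",
    "read_gene_list",
    "read_alias_map",
]

MAX_VENN_SETS = 6


@dataclass(frozen=True)
class GeneSet:
    """A labeled, deduplicated set of normalized gene symbols.

    ``provenance`` maps each member to the set of source-database names that
    contributed it; every member has at least one provenance entry.
    """

    label: str
    members: frozenset[str]
    provenance: Mapping[str, frozenset[str]] = field(default_factory=dict)

    def __post_init__(self):
        prov = dict(self.provenance)
        for g in self.members:
            if g not in prov or not prov[g]:
                prov[g] = frozenset({self.label})
        extra = set(prov) - set(self.members)
        if extra:
            raise ValidationError(
                f"provenance entries for non-members: {sorted(extra)[:5]}"
            )
        object.__setattr__(self, "provenance", prov)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))

    def sorted(self) -> list[str]:
        return sorted(self.members)

    def relabel(self, label: str) -> "GeneSet":
        return GeneSet(label, self.members, self.provenance)


@dataclass(frozen=True)
class VennResult:
    """Disjoint Venn-region decomposition of k labeled gene sets.

    ``region_counts`` maps each non-empty region signature (the frozenset of
    input labels whose sets contain the region's genes, and no others) to its
    size; ``regions`` carries the genes themselves; ``intersection`` is the
    all-sets region.
    """

    labels: tuple[str, ...]
    region_counts: Mapping[frozenset, int]
    regions: Mapping[frozenset, frozenset]
    intersection: GeneSet


def _normalize_token(tok: str) -> str:
    sym = tok.strip().upper()
    if not sym:
        raise SymbolError(f"token {tok!r} normalizes to an empty symbol")
    if any(c.isspace() for c in sym):
        # internal whitespace is collapsed out: "MMP 9" is not a symbol
        raise SymbolError(f"token {tok!r} contains internal whitespace")
    return sym


def normalize_symbols(
    raw: Iterable[str],
    alias_map: Mapping[str, str] | None = None,
    label: str = "geneset",
    source: str | None = None,
) -> tuple[GeneSet, list[str]]:
    """Normalize raw tokens into a deduplicated :class:`GeneSet`.

    Tokens are trimmed and uppercased; when ``alias_map`` is given, tokens
    found in it (case-insensitively) are replaced by their official symbol,
    and tokens *not* found are retained as-is and reported in the returned
    warning list, so set sizes stay conservative and auditable.

    Returns ``(gene_set, unmapped_warnings)``.  Empty input yields an empty
    set; a token that normalizes to the empty string raises
    :class:`~netpharm.errors.SymbolError`.
    """
    amap = None
    if alias_map is not None:
        amap = {}
        for k, v in alias_map.items():
            amap[_normalize_token(k)] = _normalize_token(v)
    src = source or label
    members: set[str] = set()
    warnings: list[str] = []
    for tok in raw:
        sym = _normalize_token(tok)
        if amap is not None:
            if sym in amap:
                sym = amap[sym]
            else:
                warnings.append(sym)
        members.add(sym)
    prov = {g: frozenset({src}) for g in members}
    return GeneSet(label, frozenset(members), prov), sorted(set(warnings))


def aggregate_sources(
    per_source: Mapping[str, GeneSet] | Sequence[tuple[str, GeneSet]],
    label: str,
) -> GeneSet:
    """Union per-source target sets into one entity-level :class:`GeneSet`.

    Provenance records every source contributing each gene, so the integrated
    set stays auditable after duplicate elimination.  Duplicate source names
    raise :class:`~netpharm.errors.LabelClashError`.
    """
    if isinstance(per_source, Mapping):
        items = list(per_source.items())
    else:
        items = list(per_source)
    names = [name for name, _ in items]
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise LabelClashError(f"duplicate source labels: {dupes}")
    members: set[str] = set()
    prov: dict[str, set[str]] = {}
    for name, gset in items:
        for g in gset.members:
            members.add(g)
            prov.setdefault(g, set()).add(name)
    return GeneSet(label, frozenset(members), {g: frozenset(s) for g, s in prov.items()})


def venn(sets: Sequence[GeneSet]) -> VennResult:
    """Decompose 2-6 gene sets into disjoint Venn regions.

    Each gene in the union is assigned to exactly one region, keyed by the
    frozenset of labels of the sets containing it; region counts therefore
    sum to the union size.  The all-sets region is also returned as a
    :class:`GeneSet` (the "intersection targets").
    """
    if len(sets) < 2:
        raise ValidationError("venn requires at least 2 sets")
    if len(sets) > MAX_VENN_SETS:
        raise ValidationError(f"venn supports at most {MAX_VENN_SETS} sets")
    labels = tuple(s.label for s in sets)
    if len(set(labels)) != len(labels):
        raise LabelClashError(f"venn requires unique labels, got {labels}")
    by_label = {s.label: s.members for s in sets}
    regions: dict[frozenset, set[str]] = {}
    union = set().union(*by_label.values())
    for g in union:
        sig = frozenset(lbl for lbl in labels if g in by_label[lbl])
        regions.setdefault(sig, set()).add(g)
    all_sig = frozenset(labels)
    inter_members = frozenset(regions.get(all_sig, set()))
    inter = GeneSet(
        "intersection(" + "&".join(labels) + ")",
        inter_members,
        {g: frozenset(labels) for g in inter_members},
    )
    return VennResult(
        labels=labels,
        region_counts={sig: len(gs) for sig, gs in regions.items()},
        regions={sig: frozenset(gs) for sig, gs in regions.items()},
        intersection=inter,
    )


def combine_related(intersection: GeneSet, associated: GeneSet, label: str = "related") -> GeneSet:
    """Union the intersection targets with the association-expanded targets.

    When the two inputs are disjoint the result size is the sum of the input
    sizes; provenance from both inputs is merged.
    """
    members = intersection.members | associated.members
    prov: dict[str, frozenset] = {}
    for g in members:
        srcs: set[str] = set()
        if g in intersection.members:
            srcs |= intersection.provenance[g]
        if g in associated.members:
            srcs |= associated.provenance[g]
        prov[g] = frozenset(srcs)
    return GeneSet(label, frozenset(members), prov)


def containment_report(inner: GeneSet, outer: GeneSet) -> tuple[bool, GeneSet]:
    """Report whether ``inner`` is fully covered by ``outer``.

    Returns ``(is_subset, missing)`` where ``missing`` holds the inner genes
    absent from the outer set.
    """
    missing = inner.members - outer.members
    gs = GeneSet(
        f"{inner.label}-not-in-{outer.label}",
        frozenset(missing),
        {g: inner.provenance[g] for g in missing},
    )
    return (not missing), gs


# ---------------------------------------------------------------------------
# plain-text I/O

def read_gene_list(path: str | Path) -> list[str]:
    """Read one symbol per line; blank lines and '#' comments are ignored."""
    out = []
    for line in Path(path).read_text(encoding="utf-8").splitlines():
        tok = line.split("#", 1)[0].strip()
        if tok:
            out.append(tok)
    return out


def read_alias_map(path: str | Path) -> dict[str, str]:
    """Read a 2-column TSV mapping alias -> official symbol."""
    amap: dict[str, str] = {}
    for i, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line.strip() or line.lstrip().startswith("#"):
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 2 or not parts[0].strip() or not parts[1].strip():
            raise ValidationError(f"{path}:{i}: expected 2 tab-separated columns")
        amap[parts[0].strip()] = parts[1].strip()
    return amap


def write_gene_list(gset: GeneSet, path: str | Path) -> None:
    Path(path).write_text("\n".join(gset.sorted()) + "\n", encoding="utf-8")


def venn_summary(result: VennResult) -> dict:
    """JSON-serializable summary of a Venn decomposition."""
    return {
        "labels": list(result.labels),
        "regions": [
            {"signature": sorted(sig), "count": result.region_counts[sig]}
            for sig in sorted(result.region_counts, key=lambda s: (len(s), sorted(s)))
        ],
        "intersection": result.intersection.sorted(),
    }
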