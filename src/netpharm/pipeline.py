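"""Config-driven orchestration of the full analysis.

Stages run in the study's flow order: per-source aggregation -> Venn
intersection -> association expansion -> PPI filtering -> consensus hubs ->
MCODE modules -> over-representation -> TF ranking -> tripartite network ->
report.  Every stage persists its outputs under the run directory and reads
its inputs from the persisted outputs of earlier stages, so any single stage
can be re-run reproducibly from disk.

Randomized stages (EPC percolation, TF permutations) draw their seeds from
the single configured seed through fixed per-stage channels, so adding a
stage never shifts another stage's randomness.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd
import yaml
from pydantic import BaseModel, ConfigDict, Field

from . import __version__
from .assoc import expand_related, read_association_tsv
from .centrality import EPCParams, consensus_hubs
from .enrich import EmptyQueryError, ora, read_gmt, rows_to_frame, tf_nes, top_terms
from .errors import NetpharmError, ValidationError
from .mcode import MCODEParams, find_modules
from .ppi import (
    drop_isolated,
    filter_confidence,
    graph_stats,
    read_edge_tsv,
    write_edge_tsv,
    write_graphml,
)
from .targets import (
    GeneSet,
    aggregate_sources,
    combine_related,
    containment_report,
    normalize_symbols,
    read_alias_map,
    read_gene_list,
    venn,
    venn_summary,
    write_gene_list,
)
from .tripartite import build_network, common_targets, export

__all__ = [
    "PipelineConfig",
    "PipelineParams",
    "load_config",
    "validate",
    "run",
    "run_stage",
    "STAGES",
]

#: fixed seed channels, one per randomized stage
_SEED_CHANNELS = {"epc": 1, "tf": 2}


def _stage_seed(seed: int, channel: str) -> int:
    rng = np.random.default_rng([seed, _SEED_CHANNELS[channel]])
    return int(rng.integers(0, 2**31))


class MCODESettings(BaseModel):
    model_config = ConfigDict(extra="forbid")
    degree_cutoff: int = 2
    node_score_cutoff: float = 0.2
    haircut: bool = True
    k_core: int = 2
    max_depth: int = 100

    def to_params(self) -> MCODEParams:
        return MCODEParams(
            degree_cutoff=self.degree_cutoff,
            node_score_cutoff=self.node_score_cutoff,
            haircut=self.haircut,
            k_core=self.k_core,
            max_depth=self.max_depth,
        )


class PipelineParams(BaseModel):
    model_config = ConfigDict(extra="forbid")
    confidence: float = 0.7
    expansion_k: int = 20
    epc_replicates: int = 1000
    epc_retention_p: float = 0.5
    mcode: MCODESettings = Field(default_factory=MCODESettings)
    top_terms_q: int = 5
    top_terms_odds_ratio: int = 3
    tf_permutations: int = 1000
    enrichment_background: Optional[int] = None


class PipelineConfig(BaseModel):
    """Validated pipeline configuration; all paths are relative to the
    directory holding the config file."""

    model_config = ConfigDict(extra="forbid")
    seed: int = 0
    drug_sources: dict[str, dict[str, str]]
    disease_sources: dict[str, dict[str, str]]
    association_network: str
    ppi_network: str
    libraries: dict[str, str]
    tf_library: str
    alias_map: Optional[str] = None
    params: PipelineParams = Field(default_factory=PipelineParams)


def load_config(path: str | Path) -> tuple[PipelineConfig, Path]:
    """Parse a YAML config; returns (config, base_dir)."""
    path = Path(path)
    data = yaml.safe_load(path.read_text(encoding="utf-8"))
    cfg = PipelineConfig.model_validate(data)
    return cfg, path.parent


def validate(cfg: PipelineConfig, base_dir: str | Path) -> list[str]:
    """Schema, range, and file-existence findings; empty when clean."""
    base = Path(base_dir)
    findings: list[str] = []
    p = cfg.params
    if not 0.0 <= p.confidence <= 1.0:
        findings.append(f"confidence {p.confidence} outside [0, 1]")
    if p.expansion_k < 1:
        findings.append(f"expansion_k {p.expansion_k} must be >= 1")
    if p.epc_replicates < 1:
        findings.append("epc_replicates must be >= 1")
    if not 0.0 <= p.epc_retention_p <= 1.0:
        findings.append("epc_retention_p outside [0, 1]")
    if not 0.0 <= p.mcode.node_score_cutoff <= 1.0:
        findings.append("mcode.node_score_cutoff outside [0, 1]")
    if p.top_terms_q < 1 or p.top_terms_odds_ratio < 1:
        findings.append("top-term counts must be >= 1")
    if p.tf_permutations < 100:
        findings.append("tf_permutations must be >= 100")
    paths = [cfg.association_network, cfg.ppi_network, cfg.tf_library]
    paths += [f for srcs in cfg.drug_sources.values() for f in srcs.values()]
    paths += [f for srcs in cfg.disease_sources.values() for f in srcs.values()]
    paths += list(cfg.libraries.values())
    if cfg.alias_map:
        paths.append(cfg.alias_map)
    for rel in paths:
        if not (base / rel).is_file():
            findings.append(f"missing input file: {rel}")
    if len(cfg.drug_sources) < 2:
        findings.append("need at least 2 drugs for common-target analysis")
    if len(cfg.disease_sources) < 1:
        findings.append("need at least 1 disease")
    return findings


# ---------------------------------------------------------------------------
# stages; each reads persisted inputs and writes persisted outputs

def _read_entity(out: Path, name: str) -> GeneSet:
    genes = read_gene_list(out / "entities" / f"{name}.txt")
    gset, _ = normalize_symbols(genes, label=name)
    return gset


def _stage_targets(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "entities").mkdir(parents=True, exist_ok=True)
    amap = read_alias_map(base / cfg.alias_map) if cfg.alias_map else None
    summary: dict = {"drugs": {}, "diseases": {}, "unmapped_warnings": {}}
    for kind, mapping in (("drugs", cfg.drug_sources), ("diseases", cfg.disease_sources)):
        for entity, sources in mapping.items():
            per_source = {}
            for sname, rel in sources.items():
                gset, warn = normalize_symbols(
                    read_gene_list(base / rel), alias_map=amap,
                    label=f"{entity}:{sname}", source=sname,
                )
                per_source[sname] = gset
                if warn:
                    summary["unmapped_warnings"][f"{entity}:{sname}"] = len(warn)
            agg = aggregate_sources(per_source, entity)
            write_gene_list(agg, out / "entities" / f"{entity}.txt")
            summary[kind][entity] = len(agg)
    drug_union = aggregate_sources(
        {d: _read_entity(out, d) for d in cfg.drug_sources}, "drug_union"
    )
    write_gene_list(drug_union, out / "entities" / "drug_union.txt")
    summary["drug_union"] = len(drug_union)
    return summary


def _stage_related(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "related").mkdir(parents=True, exist_ok=True)
    drug_union = _read_entity(out, "drug_union")
    diseases = {d: _read_entity(out, d) for d in cfg.disease_sources}
    vres = venn([drug_union] + list(diseases.values()))
    (out / "related" / "venn.json").write_text(
        json.dumps(venn_summary(vres), indent=1, sort_keys=True), encoding="utf-8"
    )
    containment = {}
    names = sorted(diseases)
    for a in names:
        for b in names:
            if a != b:
                ok, missing = containment_report(diseases[a], diseases[b])
                containment[f"{a} in {b}"] = {"is_subset": ok, "n_missing": len(missing)}
    (out / "related" / "containment.json").write_text(
        json.dumps(containment, indent=1, sort_keys=True), encoding="utf-8"
    )
    intersection = vres.intersection.relabel("intersection")
    write_gene_list(intersection, out / "related" / "intersection.txt")
    net = read_association_tsv(base / cfg.association_network)
    associated = expand_related(net, intersection, k=cfg.params.expansion_k)
    write_gene_list(associated, out / "related" / "associated.txt")
    related = combine_related(intersection, associated)
    write_gene_list(related, out / "related" / "related.txt")
    return {
        "venn_regions": {
            "|".join(sorted(sig)): c for sig, c in vres.region_counts.items()
        },
        "n_intersection": len(intersection),
        "n_associated": len(associated),
        "n_related": len(related),
        "containment": containment,
    }


def _stage_ppi(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "ppi").mkdir(parents=True, exist_ok=True)
    g = read_edge_tsv(base / cfg.ppi_network)
    raw_stats = graph_stats(g)
    filtered = drop_isolated(filter_confidence(g, cfg.params.confidence))
    write_edge_tsv(filtered, out / "ppi" / "filtered.tsv")
    write_graphml(filtered, out / "ppi" / "filtered.graphml")
    fstats = graph_stats(filtered)
    summary = {
        "raw": dict(zip(("n_nodes", "n_edges", "n_components"), raw_stats)),
        "filtered": dict(zip(("n_nodes", "n_edges", "n_components"), fstats)),
        "confidence": cfg.params.confidence,
    }
    (out / "ppi" / "stats.json").write_text(
        json.dumps(summary, indent=1, sort_keys=True), encoding="utf-8"
    )
    return summary


def _load_filtered(out: Path) -> nx.Graph:
    return read_edge_tsv(out / "ppi" / "filtered.tsv")


def _stage_hubs(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "hubs").mkdir(parents=True, exist_ok=True)
    g = _load_filtered(out)
    params = EPCParams(
        replicates=cfg.params.epc_replicates,
        retention_p=cfg.params.epc_retention_p,
        seed=_stage_seed(cfg.seed, "epc"),
    )
    result = consensus_hubs(g, params)
    table = result.table.copy()
    table["mcc"] = table["mcc"].astype(object)  # exact integers in the TSV
    table.to_csv(out / "hubs" / "centrality.tsv", sep="\t")
    payload = {
        "hubs": result.hubs.sorted(),
        "means": {k: float(v) for k, v in result.means.items()},
        "epc_seed": params.seed,
    }
    (out / "hubs" / "hubs.json").write_text(
        json.dumps(payload, indent=1, sort_keys=True), encoding="utf-8"
    )
    return {
        "n_hubs": len(result.hubs),
        "hubs": result.hubs.sorted(),
        "means": payload["means"],
    }


def _stage_modules(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "modules").mkdir(parents=True, exist_ok=True)
    g = _load_filtered(out)
    modules = find_modules(g, cfg.params.mcode.to_params())
    rows = []
    for m in modules:
        rows.append(
            {
                "rank": m.rank,
                "score": round(m.score, 6),
                "size": len(m.nodes),
                "seed": m.seed,
                "members": ";".join(m.nodes.sorted()),
            }
        )
        write_graphml(
            g.subgraph(m.nodes.members), out / "modules" / f"module_{m.rank}.graphml"
        )
    pd.DataFrame(rows, columns=["rank", "score", "size", "seed", "members"]).to_csv(
        out / "modules" / "modules.tsv", sep="\t", index=False
    )
    return {
        "n_modules": len(modules),
        "modules": [
            {"rank": r["rank"], "score": r["score"], "size": r["size"], "seed": r["seed"]}
            for r in rows
        ],
    }


def _read_modules(out: Path) -> list[GeneSet]:
    df = pd.read_csv(out / "modules" / "modules.tsv", sep="\t")
    sets = []
    for _, row in df.iterrows():
        members = frozenset(str(row["members"]).split(";"))
        sets.append(
            GeneSet(
                f"module_{int(row['rank'])}",
                members,
                {g: frozenset({"mcode"}) for g in members},
            )
        )
    return sets


def _stage_enrich(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "enrich").mkdir(parents=True, exist_ok=True)
    related, _ = normalize_symbols(
        read_gene_list(out / "related" / "related.txt"), label="related"
    )
    modules = _read_modules(out)
    summary: dict = {}
    for lib_name, rel in sorted(cfg.libraries.items()):
        lib = read_gmt(base / rel, name=lib_name)
        if cfg.params.enrichment_background:
            lib = lib.with_background(cfg.params.enrichment_background)
        rows = ora(related, lib)
        rows_to_frame(rows).to_csv(
            out / "enrich" / f"{lib_name}_all.tsv", sep="\t", index=False
        )
        top_q = top_terms(rows, by="q", k=cfg.params.top_terms_q)
        top_or = top_terms(rows, by="odds_ratio", k=cfg.params.top_terms_odds_ratio)
        rows_to_frame(top_q).to_csv(
            out / "enrich" / f"{lib_name}_top_q.tsv", sep="\t", index=False
        )
        rows_to_frame(top_or).to_csv(
            out / "enrich" / f"{lib_name}_top_or.tsv", sep="\t", index=False
        )
        mod_top = {}
        for mod in modules:
            try:
                mrows = ora(mod, lib)
            except EmptyQueryError:
                mod_top[mod.label] = []
                continue
            best = top_terms(mrows, by="odds_ratio", k=cfg.params.top_terms_odds_ratio)
            mod_top[mod.label] = [r.term for r in best]
            rows_to_frame(best).to_csv(
                out / "enrich" / f"{mod.label}_{lib_name}_top_or.tsv",
                sep="\t",
                index=False,
            )
        summary[lib_name] = {
            "top_by_q": [r.term for r in top_q],
            "top_by_odds_ratio": [r.term for r in top_or],
            "per_module_top_by_odds_ratio": mod_top,
        }
    return summary


def _stage_tf(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "tf").mkdir(parents=True, exist_ok=True)
    hubs_payload = json.loads((out / "hubs" / "hubs.json").read_text(encoding="utf-8"))
    hub_set, _ = normalize_symbols(hubs_payload["hubs"], label="core_targets")
    lib = read_gmt(base / cfg.tf_library, name="tf")
    rows = tf_nes(
        hub_set, lib, n_perm=cfg.params.tf_permutations, seed=_stage_seed(cfg.seed, "tf")
    )
    pd.DataFrame(
        {
            "rank": [r.rank for r in rows],
            "tf": [r.tf for r in rows],
            "nes": [round(r.nes, 6) for r in rows],
            "n_targets_hit": [r.n_targets_hit for r in rows],
        }
    ).to_csv(out / "tf" / "tf_ranking.tsv", sep="\t", index=False)
    return {
        "top_tfs": [
            {
                "rank": r.rank,
                "tf": r.tf,
                "nes": round(r.nes, 4),
                "n_targets_hit": r.n_targets_hit,
            }
            for r in rows[:10]
        ]
    }


def _stage_tripartite(cfg: PipelineConfig, base: Path, out: Path) -> dict:
    (out / "tripartite").mkdir(parents=True, exist_ok=True)
    related, _ = normalize_symbols(
        read_gene_list(out / "related" / "related.txt"), label="related"
    )
    drugs = {d: _read_entity(out, d) for d in cfg.drug_sources}
    diseases = {d: _read_entity(out, d) for d in cfg.disease_sources}

    def restrict(gset: GeneSet) -> GeneSet:
        keep = gset.members & related.members
        return GeneSet(gset.label, keep, {g: gset.provenance[g] for g in keep})

    net = build_network(
        {d: restrict(s) for d, s in drugs.items()},
        {d: restrict(s) for d, s in diseases.items()},
        related.relabel("all_targets"),
    )
    for fmt in ("graphml", "sif", "json"):
        export(net, out / "tripartite" / f"network.{fmt}", fmt)
    common = common_targets(drugs, restrict_to=related)
    write_gene_list(common, out / "tripartite" / "common_targets.txt")
    n_isolated = sum(
        1 for v, d in net.nodes(data=True) if d["kind"] == "target" and net.degree(v) == 0
    )
    return {
        "n_nodes": net.number_of_nodes(),
        "n_edges": net.number_of_edges(),
        "n_isolated_targets": n_isolated,
        "n_common_targets": len(common),
        "common_targets": common.sorted(),
    }


STAGES = {
    "targets": _stage_targets,
    "related": _stage_related,
    "ppi": _stage_ppi,
    "hubs": _stage_hubs,
    "modules": _stage_modules,
    "enrich": _stage_enrich,
    "tf": _stage_tf,
    "tripartite": _stage_tripartite,
}


def run_stage(name: str, cfg: PipelineConfig, base_dir: str | Path, outdir: str | Path) -> dict:
    """Run one stage from its persisted inputs."""
    if name not in STAGES:
        raise ValidationError(f"unknown stage {name!r}; choose from {list(STAGES)}")
    return STAGES[name](cfg, Path(base_dir), Path(outdir))


def run(cfg: PipelineConfig, base_dir: str | Path, outdir: str | Path) -> dict:
    """Execute all stages and write report.json / report.md.

    The report body is a pure function of the configuration and the input
    files: rerunning with the same config and seed reproduces it byte for
    byte.  A stage failure aborts with the stage name; earlier stages'
    outputs remain on disk.
    """
    findings = validate(cfg, base_dir)
    if findings:
        raise ValidationError("; ".join(findings))
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "config": json.loads(cfg.model_dump_json()),
        "seed": cfg.seed,
        "versions": {"netpharm": __version__},
        "stages": {},
    }
    for name, fn in STAGES.items():
        try:
            report["stages"][name] = fn(cfg, Path(base_dir), out)
        except NetpharmError:
            raise
        except Exception as exc:  # noqa: BLE001 - annotate the failing stage
            raise NetpharmError(f"stage {name!r} failed: {exc}") from exc
    body = json.dumps(report, indent=1, sort_keys=True)
    (out / "report.json").write_text(body, encoding="utf-8")
    (out / "report.md").write_text(_markdown_report(report), encoding="utf-8")
    return report


def _markdown_report(report: dict) -> str:
    s = report["stages"]
    lines = [
        "# Pipeline report",
        "",
        f"Seed: {report['seed']}",
        "",
        "## Target sets",
        f"- drug union: {s['targets']['drug_union']} genes "
        f"({', '.join(f'{d}: {n}' for d, n in sorted(s['targets']['drugs'].items()))})",
        "- diseases: "
        + ", ".join(f"{d}: {n}" for d, n in sorted(s["targets"]["diseases"].items())),
        "",
        "## Related targets",
        f"- intersection: {s['related']['n_intersection']}",
        f"- associated: {s['related']['n_associated']}",
        f"- related: {s['related']['n_related']}",
        "",
        "## PPI network",
        f"- filtered: {s['ppi']['filtered']['n_nodes']} nodes, "
        f"{s['ppi']['filtered']['n_edges']} edges "
        f"(confidence >= {s['ppi']['confidence']})",
        "",
        "## Core targets",
        f"- {s['hubs']['n_hubs']} hubs: {', '.join(s['hubs']['hubs'])}",
        "",
        "## Modules",
    ]
    for m in s["modules"]["modules"]:
        lines.append(
            f"- module {m['rank']}: score {m['score']}, size {m['size']}, seed {m['seed']}"
        )
    lines += ["", "## Top transcription factors"]
    for r in s["tf"]["top_tfs"]:
        lines.append(
            f"- {r['rank']}. {r['tf']} (NES {r['nes']}, targets hit {r['n_targets_hit']})"
        )
    lines += [
        "",
        "## Tripartite network",
        f"- {s['tripartite']['n_nodes']} nodes, {s['tripartite']['n_edges']} edges, "
        f"{s['tripartite']['n_isolated_targets']} isolated targets",
        f"- common drug targets ({s['tripartite']['n_common_targets']}): "
        f"{', '.join(s['tripartite']['common_targets'])}",
        "",
    ]
    return "\n".join(lines)
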