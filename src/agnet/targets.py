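"""Candidate target-process discovery: the staged subtraction cascade.

A GO biological process is a candidate drug target when it is
(1) significantly overrepresented in the disease's associative gene
network, (2) linked to the disease by a regulation-type relation in the
knowledge graph, (3) NOT overrepresented in any drug-response network of
the considered drug groups, and (4) NOT linked to any considered drug by
a regulation-type relation. The cascade applies these filters in order
and reports the count surviving each stage, so every run exposes its own
audit trail (e.g. 381 enriched -> 71 disease-regulated -> 59 after
drug-enrichment subtraction -> 11 candidates on a knowledge base planted
with those cardinalities).
"""

from __future__ import annotations

import json
import math
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .agn import member_gene_list, reconstruct_agn
from .enrichment import EnrichmentResult, GeneSetCollection, enrich
from .graph import KnowledgeGraph, KnowledgeGraphError

__all__ = [
    "DEFAULT_REGULATION_TYPES",
    "DEFAULT_REGULATION_ALIASES",
    "CascadeConfig",
    "TargetCandidate",
    "CascadeReport",
    "CascadeStageError",
    "resolve_regulation_labels",
    "filter_disease_regulated",
    "subtract_drug_enriched",
    "subtract_drug_regulated",
    "run_cascade",
    "write_report",
]

_GO_ID = re.compile(r"GO:\d{7}$")

#: Coarse regulation-type filter used for disease-process and drug-process
#: links; matching is case-insensitive and goes through the alias table.
DEFAULT_REGULATION_TYPES = frozenset({"Regulation", "Downregulation", "Upregulation"})

#: Maps each coarse filter name to the fine-grained vocabulary labels it
#: covers. The coarsening is explicit data so users can align it with
#: whatever edge-label vocabulary their knowledge base uses.
DEFAULT_REGULATION_ALIASES: dict[str, frozenset[str]] = {
    "regulation": frozenset({"regulation", "expression regulation", "activity regulation"}),
    "upregulation": frozenset(
        {"upregulation", "expression upregulation", "activity upregulation",
         "positive regulation"}
    ),
    "downregulation": frozenset(
        {"downregulation", "expression downregulation", "activity downregulation",
         "negative regulation"}
    ),
}


class CascadeStageError(RuntimeError):
    """A cascade stage failed; the message is tagged with the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"[stage: {stage}] {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class CascadeConfig:
    """Parameters of one cascade run."""

    drug_groups: dict[str, list[str]]
    regulation_types: frozenset[str] = DEFAULT_REGULATION_TYPES
    alpha: float = 0.05
    min_overlap: int = 1
    aliases: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(DEFAULT_REGULATION_ALIASES)
    )

    def __post_init__(self) -> None:
        if not self.drug_groups or any(not v for v in self.drug_groups.values()):
            raise ValueError("drug_groups must be nonempty, with nonempty member lists")
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")


def resolve_regulation_labels(cfg: CascadeConfig, g: KnowledgeGraph) -> set[str]:
    """Expand the coarse regulation filter into concrete vocabulary labels.

    Each requested filter name matches, case-insensitively, both the raw
    vocabulary labels and every label listed under it in the alias table.
    """
    wanted = {t.lower() for t in cfg.regulation_types}
    alias_map = {k.lower(): {v.lower() for v in vals} for k, vals in cfg.aliases.items()}
    resolved: set[str] = set()
    for label in g.vocabulary:
        low = label.lower()
        if low in wanted:
            resolved.add(label)
            continue
        for coarse in wanted:
            if low in alias_map.get(coarse, ()):
                resolved.add(label)
                break
    return resolved


@dataclass
class TargetCandidate:
    """A disease-enriched term with its cascade flags and final status."""

    term_id: str
    term_name: str
    p_adj_disease: float
    disease_regulated: bool
    drug_enriched: bool
    drug_regulated: bool
    status: str  # candidate | excluded_not_regulated | excluded_drug_enriched | excluded_drug_regulated

    def to_dict(self) -> dict:
        return {
            "term_id": self.term_id,
            "term_name": self.term_name,
            "p_adj_disease": self.p_adj_disease,
            "disease_regulated": self.disease_regulated,
            "drug_enriched": self.drug_enriched,
            "drug_regulated": self.drug_regulated,
            "status": self.status,
        }


def _process_node_index(g: KnowledgeGraph) -> dict[str, str]:
    """Map GO ids to process entity ids (matching by id, then by xref)."""
    index: dict[str, str] = {}
    for ent in g.entities.values():
        if ent.entity_class != "process":
            continue
        if _GO_ID.match(ent.id):
            index.setdefault(ent.id, ent.id)
        for x in ent.xrefs:
            if _GO_ID.match(x):
                index.setdefault(x, ent.id)
    return index


def _regulated_partners(
    g: KnowledgeGraph, anchor: str, labels: set[str]
) -> set[str]:
    """Process entity ids regulation-linked (either direction) to *anchor*."""
    return g.neighbors(anchor, allowed_types=labels, allowed_classes={"process"})


def filter_disease_regulated(
    enriched: Sequence[EnrichmentResult],
    g: KnowledgeGraph,
    disease: str,
    cfg: CascadeConfig,
) -> list[str]:
    """Significant enriched terms regulation-linked to the disease node.

    Terms lacking a process node with a matching GO id cannot be checked
    against the graph and are dropped with a warning.
    """
    g.entity(disease)
    labels = resolve_regulation_labels(cfg, g)
    index = _process_node_index(g)
    partners = _regulated_partners(g, disease, labels)
    out: list[str] = []
    missing: list[str] = []
    for res in enriched:
        if not res.significant:
            continue
        node = index.get(res.term_id)
        if node is None:
            missing.append(res.term_id)
            continue
        if node in partners:
            out.append(res.term_id)
    if missing:
        warnings.warn(
            f"{len(missing)} enriched term(s) have no process node in the "
            f"graph and were dropped from the regulation filter "
            f"(e.g. {missing[:3]})",
            stacklevel=2,
        )
    return out


def subtract_drug_enriched(
    disease_terms: Sequence[str],
    drug_enrichments: Mapping[str, Sequence[EnrichmentResult]],
    alpha: float = 0.05,
) -> list[str]:
    """Remove terms significant in any drug group's enrichment (union).

    Order of the surviving *disease_terms* is preserved. ``alpha`` is only
    a guard: results already carry their significance flag, but any result
    whose ``p_adj`` crosses a different alpha is re-thresholded here.
    """
    drug_sig: set[str] = set()
    for results in drug_enrichments.values():
        for res in results:
            if res.p_adj < alpha:
                drug_sig.add(res.term_id)
    return [t for t in disease_terms if t not in drug_sig]


def subtract_drug_regulated(
    terms: Sequence[str],
    g: KnowledgeGraph,
    cfg: CascadeConfig,
    enrichment_by_term: Mapping[str, EnrichmentResult] | None = None,
) -> list[TargetCandidate]:
    """Classify remaining terms by drug regulation; survivors are candidates.

    A term is drug-regulated when at least one regulation-type relation
    connects its process node to any drug configured in ``cfg.drug_groups``.
    Every input term receives a status (candidate or
    excluded_drug_regulated). *enrichment_by_term* optionally supplies the
    disease-enrichment results so candidates carry their adjusted p-value.
    """
    labels = resolve_regulation_labels(cfg, g)
    index = _process_node_index(g)
    drug_partners: set[str] = set()
    for drugs in cfg.drug_groups.values():
        for drug in drugs:
            g.entity(drug)
            drug_partners |= _regulated_partners(g, drug, labels)
    out: list[TargetCandidate] = []
    for tid in terms:
        node = index.get(tid)
        regulated = node is not None and node in drug_partners
        res = (enrichment_by_term or {}).get(tid)
        out.append(
            TargetCandidate(
                term_id=tid,
                term_name=res.term_name if res else "",
                p_adj_disease=res.p_adj if res else math.nan,
                disease_regulated=True,
                drug_enriched=False,
                drug_regulated=regulated,
                status="excluded_drug_regulated" if regulated else "candidate",
            )
        )
    return out


@dataclass
class CascadeReport:
    """Per-stage counts, parameters and the full candidate table."""

    disease: str
    stage_counts: dict[str, int]
    candidates: list[TargetCandidate]
    table: list[TargetCandidate]  # one row per significant disease term
    agn_stats: dict[str, dict]
    params: dict

    def to_dict(self) -> dict:
        return {
            "disease": self.disease,
            "stage_counts": self.stage_counts,
            "agn_stats": self.agn_stats,
            "params": self.params,
            "candidates": [c.to_dict() for c in self.candidates],
            "table": [c.to_dict() for c in self.table],
        }


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except CascadeStageError:
                raise
            except Exception as exc:
                raise CascadeStageError(name, exc) from exc
        return wrapped
    return deco


def run_cascade(
    g: KnowledgeGraph,
    disease: str,
    sets: GeneSetCollection,
    cfg: CascadeConfig,
    mapping: Mapping[str, str],
    agn_allowed_types: set[str] | None = None,
) -> CascadeReport:
    """Execute the full target-discovery cascade.

    Stages, in order: AGN reconstruction for the disease and each drug
    group; member gene lists; enrichment of each list; regulation filter
    against the disease; subtraction of the union of drug-significant
    terms; subtraction of drug-regulated terms. Deterministic given its
    inputs; errors are tagged with the stage that raised them.
    """
    from .agn import agn_stats as _agn_stats  # local to avoid cycle at import time

    # -- AGN reconstruction
    build = _stage("agn_reconstruction")(reconstruct_agn)
    disease_agn = build(g, [disease], agn_allowed_types)
    group_agns = {
        name: build(g, drugs, agn_allowed_types)
        for name, drugs in cfg.drug_groups.items()
    }

    # -- gene lists
    genes_of = _stage("gene_lists")(member_gene_list)
    disease_genes = genes_of(disease_agn, g, mapping)
    group_genes = {name: genes_of(a, g, mapping) for name, a in group_agns.items()}

    # -- enrichment (disease + one per drug group)
    run_enrich = _stage("enrichment")(enrich)
    disease_enr = run_enrich(disease_genes, sets, cfg.alpha, cfg.min_overlap)
    drug_enr = {
        name: (run_enrich(genes, sets, cfg.alpha, cfg.min_overlap) if genes else [])
        for name, genes in group_genes.items()
    }

    significant = [r for r in disease_enr if r.significant]
    by_term = {r.term_id: r for r in disease_enr}

    # -- stage 1: regulation filter against the disease
    regulated = _stage("filter_disease_regulated")(filter_disease_regulated)(
        significant, g, disease, cfg
    )
    regulated_set = set(regulated)

    # -- stage 2: subtract union of drug-enriched terms
    after_drug_enriched = _stage("subtract_drug_enriched")(subtract_drug_enriched)(
        regulated, drug_enr, cfg.alpha
    )
    drug_enriched_set = regulated_set - set(after_drug_enriched)

    # -- stage 3: subtract drug-regulated terms
    classified = _stage("subtract_drug_regulated")(subtract_drug_regulated)(
        after_drug_enriched, g, cfg, by_term
    )
    status_of = {c.term_id: c for c in classified}

    table: list[TargetCandidate] = []
    for res in significant:
        tid = res.term_id
        if tid in status_of:
            c = status_of[tid]
            c.term_name = res.term_name
            c.p_adj_disease = res.p_adj
            table.append(c)
            continue
        if tid in drug_enriched_set:
            status, reg, denr, dreg = "excluded_drug_enriched", True, True, False
        else:
            status, reg, denr, dreg = "excluded_not_regulated", False, False, False
        table.append(
            TargetCandidate(
                term_id=tid,
                term_name=res.term_name,
                p_adj_disease=res.p_adj,
                disease_regulated=reg,
                drug_enriched=denr,
                drug_regulated=dreg,
                status=status,
            )
        )
    candidates = [c for c in table if c.status == "candidate"]

    stage_counts = {
        "significant_disease_terms": len(significant),
        "disease_regulated": len(regulated),
        "after_drug_enriched_subtraction": len(after_drug_enriched),
        "drug_regulated_removed": sum(
            1 for c in classified if c.status == "excluded_drug_regulated"
        ),
        "candidates": len(candidates),
        **{
            f"significant_terms[{name}]": sum(1 for r in res if r.significant)
            for name, res in drug_enr.items()
        },
    }
    report = CascadeReport(
        disease=disease,
        stage_counts=stage_counts,
        candidates=candidates,
        table=table,
        agn_stats={
            "disease": _agn_stats(disease_agn, g).to_dict(),
            **{name: _agn_stats(a, g).to_dict() for name, a in group_agns.items()},
        },
        params={
            "alpha": cfg.alpha,
            "min_overlap": cfg.min_overlap,
            "regulation_types": sorted(cfg.regulation_types),
            "drug_groups": {k: list(v) for k, v in sorted(cfg.drug_groups.items())},
        },
    )
    return report


def write_report(report: CascadeReport, out_dir: str | Path) -> dict[str, Path]:
    """Write ``cascade_report.json`` and a candidate TSV table."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    jpath = out_dir / "cascade_report.json"
    tpath = out_dir / "candidates.tsv"
    with open(jpath, "w") as fh:
        json.dump(report.to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    frame = pd.DataFrame(
        [
            {"term_id": c.term_id, "term_name": c.term_name,
             "p_adj_disease": c.p_adj_disease}
            for c in report.candidates
        ],
        columns=["term_id", "term_name", "p_adj_disease"],
    )
    frame.to_csv(tpath, sep="\t", index=False)
    return {"report": jpath, "candidates": tpath}
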