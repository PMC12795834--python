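"""Star-topology associative gene networks (AGNs).

An AGN links one or more focus entities (a disease, or a group of drugs)
to the genes and proteins associated with them in the knowledge graph.
The topology is a star: every edge has exactly one endpoint among the
foci, and a member may carry several parallel edges to a focus, one per
interaction type — which is why edge counts typically exceed member
counts.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from .graph import (
    KnowledgeGraph,
    KnowledgeGraphError,
    Relation,
    export_sif,
)

__all__ = [
    "AssociativeGeneNetwork",
    "AgnStats",
    "reconstruct_agn",
    "agn_stats",
    "member_gene_list",
    "load_mapping",
    "write_agn",
]

_MEMBER_CLASSES = frozenset({"gene", "protein"})


@dataclass
class AssociativeGeneNetwork:
    """Foci, their gene/protein members, and the star edges between them."""

    foci: list[str]
    members: set[str]
    edges: list[Relation]

    def validate(self) -> None:
        foci = set(self.foci)
        if foci & self.members:
            raise ValueError("AGN foci and members overlap")
        touched: set[str] = set()
        for e in self.edges:
            endpoints_in_foci = (e.source in foci) + (e.target in foci)
            if endpoints_in_foci != 1:
                raise ValueError(
                    f"star topology violated by edge {e.source}->{e.target}"
                )
            touched.add(e.target if e.source in foci else e.source)
        if touched != self.members:
            raise ValueError("AGN members do not match edge endpoints")


@dataclass
class AgnStats:
    n_members: int
    n_genes: int
    n_proteins: int
    n_edges: int
    per_focus_edge_counts: dict[str, int]

    def to_dict(self) -> dict:
        return {
            "n_members": self.n_members,
            "n_genes": self.n_genes,
            "n_proteins": self.n_proteins,
            "n_edges": self.n_edges,
            "per_focus_edge_counts": dict(sorted(self.per_focus_edge_counts.items())),
        }


def reconstruct_agn(
    g: KnowledgeGraph,
    foci: Iterable[str],
    allowed_types: set[str] | None = None,
) -> AssociativeGeneNetwork:
    """Extract the star network of gene/protein neighbours of *foci*.

    Members are the gene and protein entities linked to any focus by at
    least one relation of an allowed type (default: the whole vocabulary,
    i.e. both regulatory and associative categories); all qualifying
    parallel edges are retained. Foci must not themselves be genes or
    proteins.
    """
    foci = list(foci)
    if not foci:
        raise ValueError("reconstruct_agn: at least one focus required")
    for f in foci:
        ent = g.entity(f)  # raises LookupGraphError if unknown
        if ent.entity_class in _MEMBER_CLASSES:
            raise KnowledgeGraphError(
                f"focus {f!r} is a {ent.entity_class}; AGN foci must be "
                "diseases or drugs"
            )
    if allowed_types is not None:
        unknown = set(allowed_types) - set(g.vocabulary)
        if unknown:
            raise KnowledgeGraphError(
                f"allowed_types not in vocabulary: {sorted(unknown)}"
            )
    focus_set = set(foci)
    members: set[str] = set()
    edges: list[Relation] = []
    seen: set[int] = set()  # avoid double-collecting focus-focus scans
    for f in foci:
        for rel in g.incident(f, allowed_types):
            other = rel.target if rel.source == f else rel.source
            if other in focus_set or other == f:
                continue
            if g.entities[other].entity_class not in _MEMBER_CLASSES:
                continue
            key = id(rel)
            if key in seen:
                continue
            seen.add(key)
            edges.append(rel)
            members.add(other)
    agn = AssociativeGeneNetwork(foci=foci, members=members, edges=edges)
    agn.validate()
    return agn


def agn_stats(agn: AssociativeGeneNetwork, g: KnowledgeGraph) -> AgnStats:
    """Cardinalities of an AGN: member/gene/protein/edge counts.

    ``per_focus_edge_counts`` attributes each star edge to its focus
    endpoint; the counts sum to ``n_edges``. Foci are excluded from all
    member counts.
    """
    agn.validate()
    n_genes = sum(1 for m in agn.members if g.entity(m).entity_class == "gene")
    n_proteins = sum(1 for m in agn.members if g.entity(m).entity_class == "protein")
    foci = set(agn.foci)
    per_focus = {f: 0 for f in agn.foci}
    for e in agn.edges:
        focus = e.source if e.source in foci else e.target
        per_focus[focus] += 1
    return AgnStats(
        n_members=len(agn.members),
        n_genes=n_genes,
        n_proteins=n_proteins,
        n_edges=len(agn.edges),
        per_focus_edge_counts=per_focus,
    )


def load_mapping(path: str | Path) -> dict[str, str]:
    """Read a protein-to-coding-gene table (``protein_id<TAB>gene_id``)."""
    df = pd.read_csv(
        path, sep="\t", comment="#", dtype=str, keep_default_na=False
    )
    cols = list(df.columns)
    if "protein_id" not in cols or "gene_id" not in cols:
        raise ValueError(
            f"mapping file {path} must have columns protein_id, gene_id"
        )
    return dict(zip(df["protein_id"], df["gene_id"]))


def member_gene_list(
    agn: AssociativeGeneNetwork,
    g: KnowledgeGraph,
    mapping: Mapping[str, str],
) -> set[str]:
    """Collapse AGN members to a deduplicated gene list for enrichment.

    Gene members pass through; protein members are replaced by their
    coding gene via *mapping*, so a protein and its gene contribute one
    entry. Proteins absent from the mapping are dropped with a warning
    rather than failing the run.
    """
    genes: set[str] = set()
    unmapped: list[str] = []
    for m in sorted(agn.members):
        cls = g.entity(m).entity_class
        if cls == "gene":
            genes.add(m)
        elif cls == "protein":
            if m in mapping:
                genes.add(mapping[m])
            else:
                unmapped.append(m)
    if unmapped:
        warnings.warn(
            f"{len(unmapped)} protein member(s) missing from the protein-to-gene "
            f"mapping were dropped (e.g. {unmapped[:3]})",
            stacklevel=2,
        )
    return genes


def write_agn(
    agn: AssociativeGeneNetwork, g: KnowledgeGraph, out_dir: str | Path, name: str
) -> dict[str, Path]:
    """Export an AGN as SIF plus a JSON stats report."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sif = out_dir / f"{name}.sif"
    stats_path = out_dir / f"{name}.stats.json"
    export_sif(agn.edges, sif)
    with open(stats_path, "w") as fh:
        json.dump(agn_stats(agn, g).to_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    return {"sif": sif, "stats": stats_path}
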