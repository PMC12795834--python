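"""Typed biomedical knowledge graph: data model and tab-delimited I/O.

The graph is the substrate for every downstream analysis: entities are
genes, proteins, diseases, drugs and biological processes; relations are
typed, optionally signed, and may be parallel (several relations of
different types between the same pair of entities, each describing a
distinct kind of interaction reported in the literature).

On-disk representation is three TSV tables (``entities.tsv``,
``relations.tsv``, ``vocabulary.tsv``) plus an optional SIF export for
network viewers; see :func:`load_graph` / :func:`save_graph`.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import pandas as pd

__all__ = [
    "ENTITY_CLASSES",
    "RELATION_CATEGORIES",
    "Entity",
    "RelationType",
    "Relation",
    "KnowledgeGraph",
    "KnowledgeGraphError",
    "GraphFormatError",
    "ReferentialIntegrityError",
    "VocabularyError",
    "LookupGraphError",
    "load_graph",
    "save_graph",
    "load_vocabulary",
    "export_sif",
    "relation_type_distribution",
]

#: Closed vocabulary of entity classes modelled by the pipeline. Knowledge
#: bases distinguish many more (metabolites, pathways, phenotypes, ...);
#: anything outside this set is collapsed to ``other`` on load.
ENTITY_CLASSES = frozenset({"gene", "protein", "disease", "drug", "process", "other"})

RELATION_CATEGORIES = frozenset({"regulatory", "associative"})


class KnowledgeGraphError(Exception):
    """Base class for graph construction and lookup failures."""


class GraphFormatError(KnowledgeGraphError):
    """A TSV table does not conform to the expected dialect."""


class ReferentialIntegrityError(KnowledgeGraphError):
    """A relation references an entity id that does not exist."""


class VocabularyError(KnowledgeGraphError):
    """A relation uses a type label missing from the vocabulary."""


class LookupGraphError(KnowledgeGraphError, KeyError):
    """An entity id was not found in the graph."""

    def __str__(self) -> str:  # KeyError quotes its args; keep the message plain
        return self.args[0] if self.args else ""


@dataclass(frozen=True)
class Entity:
    """A node: gene, protein, disease, drug, biological process or other."""

    id: str
    name: str
    entity_class: str
    xrefs: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.entity_class not in ENTITY_CLASSES:
            raise ValueError(
                f"entity_class {self.entity_class!r} not in {sorted(ENTITY_CLASSES)}"
            )


@dataclass(frozen=True)
class RelationType:
    """A relation label with its category and regulatory polarity.

    ``category`` separates regulatory relationships (expression/activity
    up- and down-regulation etc.) from purely associative ones (a gene is
    associated with, or is a marker of, a disease). Polarity is +1 for
    activating, -1 for inhibiting, 0 for unsigned; associative types are
    always unsigned.
    """

    label: str
    category: str
    polarity: int

    def __post_init__(self) -> None:
        if self.category not in RELATION_CATEGORIES:
            raise ValueError(f"category {self.category!r} not in {sorted(RELATION_CATEGORIES)}")
        if self.polarity not in (-1, 0, 1):
            raise ValueError(f"polarity must be -1, 0 or +1, got {self.polarity}")
        if self.category == "associative" and self.polarity != 0:
            raise ValueError(f"associative relation type {self.label!r} must have polarity 0")


@dataclass(frozen=True)
class Relation:
    """A directed typed edge; ``n_sources`` counts supporting evidence items."""

    source: str
    target: str
    rel_type: str
    n_sources: int = 1

    def __post_init__(self) -> None:
        if self.n_sources < 0:
            raise ValueError("n_sources must be nonnegative")


class KnowledgeGraph:
    """Entities plus typed, signed, possibly parallel relations.

    Relations are stored directed (source -> target); neighbourhood queries
    are undirected by default because association edges are semantically
    bidirectional, with a ``directed`` flag for mechanism extraction.
    """

    def __init__(
        self,
        entities: Iterable[Entity] = (),
        relations: Iterable[Relation] = (),
        vocabulary: Iterable[RelationType] = (),
    ) -> None:
        self.entities: dict[str, Entity] = {}
        self.vocabulary: dict[str, RelationType] = {}
        self.relations: list[Relation] = []
        self._adj: dict[str, list[tuple[int, bool]]] = {}  # id -> [(rel index, is_source)]
        for rt in vocabulary:
            self.add_relation_type(rt)
        for e in entities:
            self.add_entity(e)
        for r in relations:
            self.add_relation(r)

    # -- construction -------------------------------------------------

    def add_relation_type(self, rt: RelationType) -> None:
        if rt.label in self.vocabulary:
            raise VocabularyError(f"duplicate relation type label {rt.label!r}")
        self.vocabulary[rt.label] = rt

    def add_entity(self, entity: Entity) -> None:
        if entity.id in self.entities:
            raise GraphFormatError(f"duplicate entity id {entity.id!r}")
        self.entities[entity.id] = entity
        self._adj.setdefault(entity.id, [])

    def add_relation(self, rel: Relation) -> None:
        for endpoint in (rel.source, rel.target):
            if endpoint not in self.entities:
                raise ReferentialIntegrityError(
                    f"relation {rel.source!r}-[{rel.rel_type}]->{rel.target!r} "
                    f"references unknown entity id {endpoint!r}"
                )
        if rel.rel_type not in self.vocabulary:
            raise VocabularyError(
                f"relation type {rel.rel_type!r} is not in the vocabulary"
            )
        idx = len(self.relations)
        self.relations.append(rel)
        self._adj[rel.source].append((idx, True))
        if rel.target != rel.source:
            self._adj[rel.target].append((idx, False))

    # -- queries ------------------------------------------------------

    def __contains__(self, entity_id: str) -> bool:
        return entity_id in self.entities

    def entity(self, entity_id: str) -> Entity:
        try:
            return self.entities[entity_id]
        except KeyError:
            raise LookupGraphError(f"unknown entity id {entity_id!r}") from None

    def polarity(self, rel: Relation) -> int:
        return self.vocabulary[rel.rel_type].polarity

    def incident(
        self,
        focus: str,
        allowed_types: set[str] | None = None,
        directed: bool = False,
    ) -> Iterator[Relation]:
        """Yield relations incident to *focus* (outgoing only if *directed*)."""
        self.entity(focus)
        for idx, is_source in self._adj[focus]:
            if directed and not is_source:
                continue
            rel = self.relations[idx]
            if allowed_types is not None and rel.rel_type not in allowed_types:
                continue
            yield rel

    def neighbors(
        self,
        focus: str,
        allowed_types: set[str] | None = None,
        allowed_classes: set[str] | None = None,
        directed: bool = False,
    ) -> set[str]:
        """Entity ids linked to *focus* by at least one qualifying relation.

        Parallel edges are deduplicated; by default both edge directions
        count (association semantics). ``allowed_types`` / ``allowed_classes``
        of ``None`` mean no restriction.
        """
        out: set[str] = set()
        for rel in self.incident(focus, allowed_types, directed=directed):
            other = rel.target if rel.source == focus else rel.source
            if other == focus:
                continue
            if allowed_classes is not None and self.entities[other].entity_class not in allowed_classes:
                continue
            out.add(other)
        return out

    def relations_between(
        self, a: str, b: str, allowed_types: set[str] | None = None
    ) -> list[Relation]:
        """All relations linking *a* and *b* in either direction."""
        return [
            rel
            for rel in self.incident(a, allowed_types)
            if {rel.source, rel.target} == {a, b} or (a == b and rel.source == rel.target == a)
        ]

    def to_networkx(
        self,
        allowed_types: set[str] | None = None,
        signed_only: bool = False,
    ):
        """Build a :class:`networkx.MultiDiGraph` view for path/cycle search.

        Edge attributes: ``rel_type`` and ``polarity``. ``signed_only``
        drops polarity-0 edges, leaving only sign-bearing regulation.
        """
        import networkx as nx

        g = nx.MultiDiGraph()
        g.add_nodes_from(self.entities)
        for rel in self.relations:
            if allowed_types is not None and rel.rel_type not in allowed_types:
                continue
            pol = self.polarity(rel)
            if signed_only and pol == 0:
                continue
            g.add_edge(rel.source, rel.target, rel_type=rel.rel_type, polarity=pol)
        return g

    def subgraph(self, node_ids: Iterable[str]) -> "KnowledgeGraph":
        """Induced subgraph over *node_ids* (full vocabulary retained)."""
        keep = set(node_ids)
        for nid in keep:
            self.entity(nid)
        return KnowledgeGraph(
            entities=[self.entities[n] for n in sorted(keep)],
            relations=[r for r in self.relations if r.source in keep and r.target in keep],
            vocabulary=list(self.vocabulary.values()),
        )


# ---------------------------------------------------------------------- I/O

_ENTITY_COLUMNS = ["id", "name", "entity_class"]
_RELATION_COLUMNS = ["source_id", "target_id", "rel_type"]
_VOCAB_COLUMNS = ["label", "category", "polarity"]


def _read_tsv(path: str | Path, required: Sequence[str], what: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise GraphFormatError(f"{what} file not found: {path}")
    try:
        df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise GraphFormatError(f"{what} file {path} is empty (header row required)") from None
    for col in required:
        if col not in df.columns:
            raise GraphFormatError(f"{what} file {path} is missing required column {col!r}")
    return df

def load_vocabulary(path: str | Path) -> list[RelationType]:
    """Read relation types from ``vocabulary.tsv`` (label, category, polarity)."""
    df = _read_tsv(path, _VOCAB_COLUMNS, "vocabulary")
    out = []
    for row in df.itertuples(index=False):
        try:
            pol = int(row.polarity)
        except ValueError:
            raise GraphFormatError(
                f"vocabulary polarity must be an integer, got {row.polarity!r}"
            ) from None
        try:
            out.append(RelationType(label=row.label, category=row.category, polarity=pol))
        except ValueError as exc:
            raise GraphFormatError(str(exc)) from None
    return out


def load_graph(
    entities_path: str | Path,
    relations_path: str | Path,
    vocabulary_path: str | Path,
) -> KnowledgeGraph:
    """Load a knowledge graph from its three TSV tables.

    Entity rows with an unrecognised class load as ``other`` with a warning
    naming the row; a relation referencing an unknown entity id or relation
    type raises (referential integrity is not negotiable).
    """
    vocab = load_vocabulary(vocabulary_path)
    g = KnowledgeGraph(vocabulary=vocab)

    edf = _read_tsv(entities_path, _ENTITY_COLUMNS, "entities")
    for i, row in enumerate(edf.itertuples(index=False)):
        cls = row.entity_class
        if cls not in ENTITY_CLASSES:
            warnings.warn(
                f"{entities_path}: row {i + 2}: unknown entity_class {cls!r} "
                f"for entity {row.id!r}; loading as 'other'",
                stacklevel=2,
            )
            cls = "other"
        xrefs: tuple[str, ...] = ()
        if "xrefs" in edf.columns and row.xrefs:
            xrefs = tuple(row.xrefs.split("|"))
        g.add_entity(Entity(id=row.id, name=row.name, entity_class=cls, xrefs=xrefs))

    rdf = _read_tsv(relations_path, _RELATION_COLUMNS, "relations")
    has_sources = "n_sources" in rdf.columns
    for i, row in enumerate(rdf.itertuples(index=False)):
        n_sources = 1
        if has_sources and row.n_sources:
            try:
                n_sources = int(row.n_sources)
            except ValueError:
                raise GraphFormatError(
                    f"{relations_path}: row {i + 2}: n_sources must be an "
                    f"integer, got {row.n_sources!r}"
                ) from None
        g.add_relation(
            Relation(source=row.source_id, target=row.target_id,
                     rel_type=row.rel_type, n_sources=n_sources)
        )
    return g


def save_graph(g: KnowledgeGraph, out_dir: str | Path) -> dict[str, Path]:
    """Write ``entities.tsv``, ``relations.tsv``, ``vocabulary.tsv`` to *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "entities": out_dir / "entities.tsv",
        "relations": out_dir / "relations.tsv",
        "vocabulary": out_dir / "vocabulary.tsv",
    }
    ents = pd.DataFrame(
        [
            {"id": e.id, "name": e.name, "entity_class": e.entity_class,
             "xrefs": "|".join(e.xrefs)}
            for e in g.entities.values()
        ],
        columns=_ENTITY_COLUMNS + ["xrefs"],
    )
    ents.to_csv(paths["entities"], sep="\t", index=False)
    rels = pd.DataFrame(
        [
            {"source_id": r.source, "target_id": r.target,
             "rel_type": r.rel_type, "n_sources": r.n_sources}
            for r in g.relations
        ],
        columns=_RELATION_COLUMNS + ["n_sources"],
    )
    rels.to_csv(paths["relations"], sep="\t", index=False)
    voc = pd.DataFrame(
        [
            {"label": t.label, "category": t.category, "polarity": t.polarity}
            for t in g.vocabulary.values()
        ],
        columns=_VOCAB_COLUMNS,
    )
    voc.to_csv(paths["vocabulary"], sep="\t", index=False)
    return paths


def export_sif(relations: Iterable[Relation], path: str | Path) -> None:
    """Write relations in SIF (``source<TAB>rel_type<TAB>target``)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for rel in relations:
            fh.write(f"{rel.source}\t{rel.rel_type}\t{rel.target}\n")


def relation_type_distribution(
    g: KnowledgeGraph, edges: Sequence[Relation] | None = None
) -> pd.DataFrame:
    """Tabulate relation types in *edges* (default: all of *g*'s relations).

    Returns a DataFrame with columns ``rel_type``, ``count``, ``percent``,
    sorted by count descending then label; percents sum to 100 within
    rounding. Raises :class:`ValueError` on an empty edge set.
    """
    if edges is None:
        edges = g.relations
    edges = list(edges)
    if not edges:
        raise ValueError("relation_type_distribution: empty edge set")
    counts = Counter(r.rel_type for r in edges)
    total = len(edges)
    rows = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    return pd.DataFrame(
        [{"rel_type": t, "count": c, "percent": 100.0 * c / total} for t, c in rows]
    )
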