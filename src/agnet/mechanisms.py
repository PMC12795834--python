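"""Signed regulatory mechanism extraction: paths and feedback loops.

Beyond star-shaped association networks, a typed knowledge graph supports
reconstructing the mechanism by which one molecule regulates another: a
chain of signed regulation edges. The sign of a path is the product of
its edge polarities (+1 activating, -1 inhibiting), so e.g. two mutually
activating genes form a positive feedback loop — the archetype being the
IL1B/WNT5A expression loop in rheumatoid arthritis.

Associative (unsigned) edges carry no polarity and are excluded from
sign-bearing paths by default; they may be admitted as sign-neutral via
``include_unsigned``, in which case affected paths are reported with an
undefined sign (``sign=0``) and loops touching them are left
unclassified.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx

from .graph import KnowledgeGraph, Relation, export_sif

__all__ = [
    "SignedPath",
    "FeedbackLoop",
    "find_paths",
    "find_feedback_loops",
    "mechanism_subnetwork",
    "write_paths",
    "write_loops",
]


@dataclass(frozen=True)
class SignedPath:
    """A directed chain of regulation edges with its overall sign."""

    nodes: tuple[str, ...]
    edges: tuple[Relation, ...]
    sign: int  # +1, -1, or 0 for paths containing unsigned edges

    def __post_init__(self) -> None:
        if len(self.nodes) != len(self.edges) + 1:
            raise ValueError("path must have one more node than edges")
        for (u, v), e in zip(itertools.pairwise(self.nodes), self.edges):
            if e.source != u or e.target != v:
                raise ValueError("path edges must chain head-to-tail")

    def __len__(self) -> int:
        return len(self.edges)


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle, classified by the sign of its edge product."""

    cycle: SignedPath
    loop_class: str  # positive | negative | unclassified

    def __post_init__(self) -> None:
        if self.cycle.nodes[0] != self.cycle.nodes[-1]:
            raise ValueError("loop path must start and end at the same node")
        expected = {1: "positive", -1: "negative", 0: "unclassified"}[self.cycle.sign]
        if self.loop_class != expected:
            raise ValueError(
                f"loop_class {self.loop_class!r} inconsistent with sign {self.cycle.sign}"
            )


def _signed_labels(g: KnowledgeGraph, allowed_types: set[str] | None, include_unsigned: bool) -> set[str]:
    if allowed_types is None:
        allowed = {
            t.label
            for t in g.vocabulary.values()
            if t.category == "regulatory" and (include_unsigned or t.polarity != 0)
        }
        return allowed
    unknown = set(allowed_types) - set(g.vocabulary)
    if unknown:
        raise KeyError(f"allowed_types not in vocabulary: {sorted(unknown)}")
    if not include_unsigned:
        unsigned = {t for t in allowed_types if g.vocabulary[t].polarity == 0}
        if unsigned:
            raise ValueError(
                "sign-bearing search requires signed relation types; "
                f"unsigned labels supplied: {sorted(unsigned)} "
                "(pass include_unsigned=True to admit them)"
            )
    return set(allowed_types)


def _path_from_edge_seq(g: KnowledgeGraph, view: nx.MultiDiGraph, edge_seq) -> SignedPath:
    nodes = [edge_seq[0][0]] + [e[1] for e in edge_seq]
    rels = []
    sign = 1
    for u, v, key in edge_seq:
        data = view[u][v][key]
        rels.append(Relation(source=u, target=v, rel_type=data["rel_type"]))
        pol = data["polarity"]
        sign = 0 if (sign == 0 or pol == 0) else sign * pol
    return SignedPath(nodes=tuple(nodes), edges=tuple(rels), sign=sign)


def _sort_key(p: SignedPath):
    return (len(p.edges), p.nodes, tuple(e.rel_type for e in p.edges))


def find_paths(
    g: KnowledgeGraph,
    sources: Iterable[str],
    targets: Iterable[str],
    max_len: int = 4,
    allowed_types: set[str] | None = None,
    include_unsigned: bool = False,
) -> list[SignedPath]:
    """All simple directed paths from any source to any target.

    Paths have length <= *max_len* edges; parallel edges between a node
    pair yield distinct paths (each relation type is a distinct mechanism
    hypothesis). A source equal to a target yields the simple cycles
    through that node. Output order is deterministic: by length, then
    node sequence, then edge labels.
    """
    if max_len < 1:
        raise ValueError(f"max_len must be >= 1, got {max_len}")
    sources, targets = list(sources), list(targets)
    for nid in set(sources) | set(targets):
        g.entity(nid)
    labels = _signed_labels(g, allowed_types, include_unsigned)
    view = g.to_networkx(allowed_types=labels, signed_only=not include_unsigned)

    out: list[SignedPath] = []
    for s in sorted(set(sources)):
        for t in sorted(set(targets)):
            if s != t:
                for edge_seq in nx.all_simple_edge_paths(view, s, t, cutoff=max_len):
                    out.append(_path_from_edge_seq(g, view, edge_seq))
            else:
                # cycles through s: a first hop s -> v, then simple paths v -> s
                for u, v, key in view.out_edges(s, keys=True):
                    first = (u, v, key)
                    if v == s:  # self-loop
                        out.append(_path_from_edge_seq(g, view, [first]))
                        continue
                    for tail in nx.all_simple_edge_paths(view, v, s, cutoff=max_len - 1):
                        if any(e[0] == s for e in tail):
                            continue
                        out.append(_path_from_edge_seq(g, view, [first, *tail]))
    out.sort(key=_sort_key)
    return out


def _canonical_rotation(nodes: Sequence[str]) -> int:
    """Index of the lexicographically smallest node in a simple cycle."""
    return min(range(len(nodes)), key=lambda i: nodes[i])


def find_feedback_loops(
    g: KnowledgeGraph,
    max_len: int = 4,
    allowed_types: set[str] | None = None,
    include_unsigned: bool = False,
) -> list[FeedbackLoop]:
    """All simple directed cycles of length <= *max_len*, classified by sign.

    Each cycle is reported once per combination of parallel edges, in a
    canonical rotation starting at its lexicographically smallest node,
    so the result is independent of node insertion order. Cycles with
    polarity product +1 are positive feedback loops, -1 negative.
    """
    if max_len < 2:
        raise ValueError(f"max_len must be >= 2, got {max_len}")
    labels = _signed_labels(g, allowed_types, include_unsigned)
    view = g.to_networkx(allowed_types=labels, signed_only=not include_unsigned)

    loops: list[FeedbackLoop] = []
    seen_node_cycles: set[tuple[str, ...]] = set()
    for cyc in nx.simple_cycles(view, length_bound=max_len):
        start = _canonical_rotation(cyc)
        nodes = tuple(cyc[start:] + cyc[:start])
        if nodes in seen_node_cycles:
            continue
        seen_node_cycles.add(nodes)
        hops = list(itertools.pairwise(nodes + (nodes[0],)))
        # expand every combination of parallel edges along the cycle
        choices = []
        for u, v in hops:
            keys = sorted(view[u][v], key=lambda k: view[u][v][k]["rel_type"])
            choices.append([(u, v, k) for k in keys])
        for combo in itertools.product(*choices):
            path = _path_from_edge_seq(g, view, list(combo))
            cls = {1: "positive", -1: "negative", 0: "unclassified"}[path.sign]
            loops.append(FeedbackLoop(cycle=path, loop_class=cls))
    loops.sort(key=lambda l: _sort_key(l.cycle))
    return loops


def mechanism_subnetwork(
    g: KnowledgeGraph,
    seed_entities: Iterable[str],
    max_len: int = 4,
    allowed_types: set[str] | None = None,
    include_unsigned: bool = False,
) -> KnowledgeGraph:
    """Induced subgraph over all mechanism paths between seed entities.

    Collects every node on a simple signed path between any ordered pair
    of seeds (including cycles through a single seed) and returns the
    induced knowledge graph; with no connecting paths the result is just
    the seed entities themselves.
    """
    seeds = sorted(set(seed_entities))
    for s in seeds:
        g.entity(s)
    nodes: set[str] = set(seeds)
    paths = find_paths(
        g, seeds, seeds, max_len=max_len,
        allowed_types=allowed_types, include_unsigned=include_unsigned,
    )
    for p in paths:
        nodes.update(p.nodes)
    return g.subgraph(nodes)


def _path_dict(p: SignedPath) -> dict:
    return {
        "nodes": list(p.nodes),
        "edges": [
            {"source": e.source, "rel_type": e.rel_type, "target": e.target}
            for e in p.edges
        ],
        "sign": p.sign,
    }


def write_paths(paths: Sequence[SignedPath], out_path: str | Path) -> None:
    """Dump paths as JSON (node list, edge labels, sign)."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump([_path_dict(p) for p in paths], fh, indent=2)
        fh.write("\n")


def write_loops(loops: Sequence[FeedbackLoop], out_path: str | Path, sif_path: str | Path | None = None) -> None:
    """Dump loops as JSON, optionally with a SIF of their edges."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    with open(out_path, "w") as fh:
        json.dump(
            [{"loop_class": l.loop_class, **_path_dict(l.cycle)} for l in loops],
            fh, indent=2,
        )
        fh.write("\n")
    if sif_path is not None:
        edges = []
        seen = set()
        for l in loops:
            for e in l.cycle.edges:
                key = (e.source, e.rel_type, e.target)
                if key not in seen:
                    seen.add(key)
                    edges.append(e)
        export_sif(edges, sif_path)
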