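"""Shared fixtures and independent brute-force oracles.

The oracles deliberately avoid the library's own code paths (and
networkx): neighbourhoods and star networks are recomputed by exhaustive
scans of the relation table, hypergeometric tails by exact integer
arithmetic, and paths/cycles by a direct recursive enumeration.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest

from agnet.graph import Entity, KnowledgeGraph, Relation
from agnet.synthetic import (
    GeneratorParams,
    default_vocabulary,
    generate,
    small_params,
)

# ------------------------------------------------------------------ oracles


def exact_hypergeom_tail(k: int, n: int, K: int, N: int) -> float:
    """P[X >= k] by exact integer enumeration of the hypergeometric sum."""
    num = sum(comb(K, i) * comb(N - K, n - i) for i in range(k, min(n, K) + 1))
    return num / comb(N, n)


def exact_tail_suffix(n: int, K: int, N: int) -> list[float]:
    """Exact tails P[X >= k] for every k in [0, min(n, K)] at fixed margins."""
    kmax = min(n, K)
    pmf_num = [comb(K, i) * comb(N - K, n - i) for i in range(kmax + 1)]
    denom = comb(N, n)
    suffix = list(itertools.accumulate(reversed(pmf_num)))
    return [s / denom for s in reversed(suffix)]


def scan_neighbors(g: KnowledgeGraph, focus, allowed_types=None, allowed_classes=None):
    """Exhaustive relation-table scan replicating the neighbours contract."""
    out = set()
    for rel in g.relations:
        if focus not in (rel.source, rel.target):
            continue
        if allowed_types is not None and rel.rel_type not in allowed_types:
            continue
        other = rel.target if rel.source == focus else rel.source
        if other == focus:
            continue
        if allowed_classes is not None and g.entities[other].entity_class not in allowed_classes:
            continue
        out.add(other)
    return out


def scan_agn(g: KnowledgeGraph, foci, allowed_types=None):
    """Exhaustive scan for star members and edges around *foci*."""
    foci = set(foci)
    members, edges = set(), []
    for rel in g.relations:
        in_foci = (rel.source in foci) + (rel.target in foci)
        if in_foci != 1:
            continue
        if allowed_types is not None and rel.rel_type not in allowed_types:
            continue
        other = rel.target if rel.source in foci else rel.source
        if g.entities[other].entity_class not in ("gene", "protein"):
            continue
        members.add(other)
        edges.append(rel)
    return members, edges


def enumerate_paths(g: KnowledgeGraph, sources, targets, max_len, labels):
    """Recursive enumeration of simple signed directed paths (no networkx).

    Returns a set of hashable path signatures:
    (nodes, rel_type sequence, sign).
    """
    by_source: dict[str, list[Relation]] = {}
    for rel in g.relations:
        if rel.rel_type in labels:
            by_source.setdefault(rel.source, []).append(rel)

    found = set()

    def walk(node, target, visited, nodes, rels, sign):
        if len(rels) > max_len:
            return
        if rels and node == target:
            found.add((tuple(nodes), tuple(r.rel_type for r in rels), sign))
            return
        if len(rels) == max_len:
            return
        for rel in by_source.get(node, []):
            nxt = rel.target
            if nxt in visited and nxt != target:
                continue
            if nxt == target and nxt in visited and nxt != nodes[0]:
                continue
            pol = g.vocabulary[rel.rel_type].polarity
            walk(
                nxt, target,
                visited | {nxt},
                nodes + [nxt], rels + [rel],
                0 if (sign == 0 or pol == 0) else sign * pol,
            )

    for s in set(sources):
        for t in set(targets):
            walk(s, t, {s}, [s], [], 1)
    return found


def enumerate_loops(g: KnowledgeGraph, max_len, labels):
    """All simple directed cycles by brute force, in canonical rotation.

    Returns a set of signatures ((n0, ..., n0), rel_types, sign) rotated
    to start at the lexicographically smallest node.
    """
    raw = set()
    for start in g.entities:
        for nodes, types, sign in enumerate_paths(g, [start], [start], max_len, labels):
            cyc = nodes[:-1]
            i = min(range(len(cyc)), key=lambda j: cyc[j])
            rot_nodes = cyc[i:] + cyc[:i] + (cyc[i],)
            rot_types = types[i:] + types[:i]
            raw.add((rot_nodes, rot_types, sign))
    return raw


# ---------------------------------------------------------------- builders


def make_random_graph(
    seed: int,
    n_nodes: int = 50,
    n_edges: int = 120,
    classes=("gene", "protein", "disease", "drug", "process"),
) -> KnowledgeGraph:
    """A random typed multigraph over the default vocabulary."""
    rng = np.random.default_rng(seed)
    g = KnowledgeGraph(vocabulary=default_vocabulary())
    labels = sorted(g.vocabulary)
    ids = [f"n{i:03d}" for i in range(n_nodes)]
    for nid in ids:
        cls = classes[int(rng.integers(len(classes)))]
        g.add_entity(Entity(id=nid, name=nid, entity_class=cls))
    seen = set()
    for _ in range(n_edges):
        s, t = (ids[int(rng.integers(n_nodes))] for _ in range(2))
        lab = labels[int(rng.integers(len(labels)))]
        if (s, t, lab) in seen:  # parallel edges must differ in type
            continue
        seen.add((s, t, lab))
        g.add_relation(Relation(source=s, target=t, rel_type=lab))
    return g


def make_signed_digraph(seed: int, n_nodes: int = 8, n_edges: int = 18) -> KnowledgeGraph:
    """A small random digraph restricted to signed regulatory edge types."""
    rng = np.random.default_rng(seed)
    g = KnowledgeGraph(vocabulary=default_vocabulary())
    signed = sorted(t.label for t in g.vocabulary.values()
                    if t.category == "regulatory" and t.polarity != 0)
    ids = [f"v{i}" for i in range(n_nodes)]
    for nid in ids:
        g.add_entity(Entity(id=nid, name=nid, entity_class="gene"))
    seen = set()
    for _ in range(n_edges):
        s, t = (ids[int(rng.integers(n_nodes))] for _ in range(2))
        lab = signed[int(rng.integers(len(signed)))]
        if (s, t, lab) in seen:
            continue
        seen.add((s, t, lab))
        g.add_relation(Relation(source=s, target=t, rel_type=lab))
    return g


SIGNED_LABELS = sorted(
    t.label for t in default_vocabulary()
    if t.category == "regulatory" and t.polarity != 0
)


# ---------------------------------------------------------------- fixtures


@pytest.fixture(scope="session")
def small_bundle():
    """Desk-scale exact-mode bundle (graph, gene sets, mapping, truth)."""
    return generate(small_params(seed=1))


@pytest.fixture(scope="session")
def study_bundle():
    """Study-scale exact-mode bundle with the published cardinalities."""
    from agnet.synthetic import study_scale_params

    return generate(study_scale_params(seed=1))
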