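"""Synthetic ANDSystem-style knowledge graphs with planted structure.

Real curated knowledge bases are proprietary snapshots, so every stage of
the pipeline is exercised against generated data instead: a
star-dominated disease neighbourhood of genes and proteins carrying
multi-typed parallel edges, per-drug response neighbourhoods, GO-style
gene sets with planted enrichments, planted regulation links driving the
target cascade, and planted signed feedback loops. A ``truth.json``
record accompanies every generated bundle so recovery can be asserted.

Two generation modes:

* **exact** (default): planted cardinalities are assigned by
  construction, not sampling — term gene sets are subsets of the relevant
  query gene lists (or of background genes), which forces the
  hypergeometric p-values to extremes on either side of the Bonferroni
  threshold. Stage counts of the cascade are then reproduced exactly on
  every seed; the shipped defaults carry study-scale
  rheumatoid-arthritis cardinalities (4,685 disease-network members with 9,877 edges; cascade counts
  381 / 71 / 59 / 11).
* **stochastic**: term membership is sampled, with ``planted_effect``
  controlling the fraction of each planted term drawn from the disease
  query; used for statistical property checks (planted-signal recovery,
  null behaviour, relation-type sampling weights).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .enrichment import GeneSetCollection
from .graph import (
    Entity,
    KnowledgeGraph,
    Relation,
    RelationType,
    save_graph,
)

__all__ = [
    "REGULATORY_LABELS",
    "ASSOCIATIVE_LABELS",
    "DEFAULT_REL_TYPE_WEIGHTS",
    "default_vocabulary",
    "GeneratorParams",
    "GeneratedData",
    "generate",
    "generate_wnt_loop_fixture",
    "study_scale_params",
    "small_params",
    "write_gmt",
]

#: Nine regulatory relation types (signed where the semantics give a sign).
REGULATORY_LABELS: dict[str, int] = {
    "expression upregulation": 1,
    "expression downregulation": -1,
    "expression regulation": 0,
    "activity upregulation": 1,
    "activity downregulation": -1,
    "activity regulation": 0,
    "positive regulation": 1,
    "negative regulation": -1,
    "regulation": 0,
}

#: Five associative relation types (always unsigned).
ASSOCIATIVE_LABELS: tuple[str, ...] = (
    "association",
    "interaction",
    "marker",
    "participation",
    "risk factor",
)

#: Sampling weights skew toward expression-regulation types, emulating a
#: knowledge base in which regulation of gene expression predominates.
DEFAULT_REL_TYPE_WEIGHTS: dict[str, float] = {
    "expression upregulation": 0.22,
    "expression downregulation": 0.18,
    "expression regulation": 0.15,
    "activity regulation": 0.08,
    "activity upregulation": 0.05,
    "activity downregulation": 0.05,
    "positive regulation": 0.04,
    "negative regulation": 0.03,
    "regulation": 0.05,
    "association": 0.06,
    "interaction": 0.04,
    "marker": 0.02,
    "participation": 0.02,
    "risk factor": 0.01,
}


def default_vocabulary() -> list[RelationType]:
    """The shipped 14-type relation vocabulary (9 regulatory + 5 associative)."""
    out = [
        RelationType(label=lab, category="regulatory", polarity=pol)
        for lab, pol in REGULATORY_LABELS.items()
    ]
    out += [
        RelationType(label=lab, category="associative", polarity=0)
        for lab in ASSOCIATIVE_LABELS
    ]
    return out


@dataclass
class GeneratorParams:
    """Knobs of the generator; defaults reproduce the study-scale fixture."""

    seed: int = 0
    # disease neighbourhood
    n_genes: int = 2178
    n_proteins: int = 2507
    n_background_genes: int = 7822  # genes outside the disease network (universe filler)
    disease_edges: int = 9877
    # drug-response neighbourhoods: group -> {drug name -> incident edge count}
    drug_groups: dict[str, dict[str, int]] = field(
        default_factory=lambda: {
            "csDMARD": {
                "methotrexate": 160,
                "hydroxychloroquine": 73,
                "sulfasalazine": 26,
                "leflunomide": 17,
            },
            "tsDMARD": {"tofacitinib": 60, "baricitinib": 26},
        }
    )
    # group -> (member genes, member proteins); members are shared with the
    # disease neighbourhood (drug-response genes are also disease genes)
    group_members: dict[str, tuple[int, int]] = field(
        default_factory=lambda: {"csDMARD": (151, 106), "tsDMARD": (51, 22)}
    )
    rel_type_weights: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_REL_TYPE_WEIGHTS)
    )
    # gene sets
    n_terms: int = 500
    term_size: int = 25
    planted_enriched_terms: int = 381
    planted_effect: float = 1.0  # stochastic mode: fraction of a planted term inside the query
    # cascade planting
    planted_disease_regulated: int = 71
    planted_drug_enriched_overlap: int = 12
    planted_drug_regulated: int = 48
    drug_sig_counts: dict[str, int] = field(
        default_factory=lambda: {"csDMARD": 64, "tsDMARD": 44}
    )
    # signed feedback loops among member genes: one tuple of edge polarities per loop
    planted_loops: list[tuple[int, ...]] = field(default_factory=lambda: [(1, 1)])
    exact_mode: bool = True

    # ---- derived layout ---------------------------------------------

    def group_slices(self) -> dict[str, tuple[range, range]]:
        """Per-group (gene index range, protein index range) assignments."""
        out: dict[str, tuple[range, range]] = {}
        offset = 0
        for name in sorted(self.group_members):
            ng, np_ = self.group_members[name]
            out[name] = (range(offset, offset + ng), range(offset, offset + np_))
            offset += ng
        return out

    def overlap_shares(self) -> dict[str, int]:
        """Split of the drug-enrichment overlap across groups (largest remainder)."""
        names = sorted(self.drug_sig_counts)
        total_sig = sum(self.drug_sig_counts.values())
        if self.planted_drug_enriched_overlap == 0 or total_sig == 0:
            return {n: 0 for n in names}
        exact = {
            n: self.planted_drug_enriched_overlap * self.drug_sig_counts[n] / total_sig
            for n in names
        }
        shares = {n: int(exact[n]) for n in names}
        rest = self.planted_drug_enriched_overlap - sum(shares.values())
        for n in sorted(names, key=lambda n: (-(exact[n] - shares[n]), n))[:rest]:
            shares[n] += 1
        return shares

    def validate(self) -> None:
        errors: list[str] = []
        if self.n_genes < 0 or self.n_proteins < 0 or self.n_background_genes < 0:
            errors.append("entity counts must be nonnegative")
        if self.n_proteins > 0 and self.n_genes == 0:
            errors.append("proteins require at least one gene to map onto")
        members = self.n_genes + self.n_proteins
        if members > 0 and self.disease_edges < members:
            errors.append(
                f"disease_edges ({self.disease_edges}) must cover every member once "
                f"({members})"
            )
        labels = set(REGULATORY_LABELS) | set(ASSOCIATIVE_LABELS)
        if set(self.rel_type_weights) - labels:
            errors.append("rel_type_weights contains labels outside the vocabulary")
        w = np.array(list(self.rel_type_weights.values()), dtype=float)
        if w.size == 0 or np.any(w < 0) or w.sum() == 0:
            errors.append("rel_type_weights must be nonnegative and not all zero")
        if set(self.drug_groups) != set(self.group_members):
            errors.append("drug_groups and group_members must name the same groups")
        if self.drug_groups and set(self.drug_sig_counts) != set(self.drug_groups):
            errors.append("drug_sig_counts must name exactly the drug groups")
        offset = 0
        for name in sorted(self.group_members):
            ng, np_ = self.group_members[name]
            edges = sum(self.drug_groups.get(name, {}).values())
            if np_ > ng:
                errors.append(
                    f"group {name}: protein members ({np_}) exceed gene members ({ng}); "
                    "proteins must map onto the group's own genes"
                )
            if edges < ng + np_:
                errors.append(
                    f"group {name}: edges ({edges}) must cover every member once ({ng + np_})"
                )
            offset += ng
            if offset + np_ - ng > self.n_proteins or offset > self.n_genes:
                errors.append(f"group {name}: member slice exceeds available genes/proteins")
        if self.planted_enriched_terms > self.n_terms:
            errors.append("planted_enriched_terms exceeds n_terms")
        if self.planted_disease_regulated > self.planted_enriched_terms:
            errors.append("planted_disease_regulated exceeds planted_enriched_terms")
        if self.planted_drug_enriched_overlap > self.planted_disease_regulated:
            errors.append("planted_drug_enriched_overlap exceeds planted_disease_regulated")
        if (
            self.planted_drug_regulated
            > self.planted_disease_regulated - self.planted_drug_enriched_overlap
        ):
            errors.append(
                "planted_drug_regulated exceeds the disease-regulated terms surviving "
                "drug-enrichment subtraction"
            )
        if self.planted_drug_enriched_overlap > 0 and not self.drug_groups:
            errors.append("a drug-enrichment overlap requires drug groups")
        if self.drug_groups:
            shares = self.overlap_shares()
            extras = 0
            for name in sorted(self.drug_sig_counts):
                if shares[name] > self.drug_sig_counts[name]:
                    errors.append(
                        f"group {name}: overlap share ({shares[name]}) exceeds its "
                        f"significant-term count ({self.drug_sig_counts[name]})"
                    )
                extras += self.drug_sig_counts[name] - min(
                    shares[name], self.drug_sig_counts[name]
                )
            if extras > self.planted_enriched_terms - self.planted_disease_regulated:
                errors.append(
                    "drug-only significant terms do not fit among the non-regulated "
                    "disease-enriched terms"
                )
            for name, (rng_g, _) in self.group_slices().items():
                needs_terms = self.drug_sig_counts.get(name, 0) > 0
                if needs_terms and len(rng_g) < self.term_size:
                    errors.append(
                        f"group {name}: gene members ({len(rng_g)}) smaller than "
                        f"term_size ({self.term_size})"
                    )
        reserved = sum(ng for ng, _ in self.group_members.values())
        if self.planted_enriched_terms > 0 and self.n_genes - reserved < self.term_size:
            errors.append("not enough disease-only genes to fill planted terms")
        if self.n_terms > self.planted_enriched_terms and self.n_background_genes < self.term_size:
            errors.append("not enough background genes to fill null terms")
        for spec in self.planted_loops:
            if len(spec) < 1 or any(p not in (-1, 1) for p in spec):
                errors.append(f"invalid loop polarity spec {spec!r}")
        if sum(len(s) for s in self.planted_loops) > self.n_genes:
            errors.append("planted loops need more distinct genes than available")
        if not 0 < self.planted_effect <= 1:
            errors.append("planted_effect must be in (0, 1]")
        if errors:
            raise ValueError(
                "invalid GeneratorParams:\n  - " + "\n  - ".join(errors)
            )


@dataclass
class GeneratedData:
    """A generated bundle: graph, gene sets, protein map, ground truth."""

    graph: KnowledgeGraph
    sets: GeneSetCollection
    mapping: dict[str, str]
    truth: dict
    paths: dict[str, Path] | None = None


def study_scale_params(seed: int = 0, exact: bool = True) -> GeneratorParams:
    """Study-scale preset (defaults of :class:`GeneratorParams`)."""
    return GeneratorParams(seed=seed, exact_mode=exact)


def small_params(seed: int = 0, exact: bool = True) -> GeneratorParams:
    """Desk-scale preset for fast tests and examples (cascade 40/12/8/3)."""
    return GeneratorParams(
        seed=seed,
        n_genes=120,
        n_proteins=80,
        n_background_genes=300,
        disease_edges=450,
        drug_groups={
            "csDMARD": {"drugA": 40, "drugB": 15},
            "tsDMARD": {"drugC": 20},
        },
        group_members={"csDMARD": (20, 10), "tsDMARD": (12, 4)},
        n_terms=60,
        term_size=8,
        planted_enriched_terms=40,
        planted_disease_regulated=12,
        planted_drug_enriched_overlap=4,
        planted_drug_regulated=5,
        drug_sig_counts={"csDMARD": 10, "tsDMARD": 6},
        exact_mode=exact,
    )


# ---------------------------------------------------------------- helpers


def _sample_label(rng: np.random.Generator, labels: list[str], probs: np.ndarray,
                  used: set[str]) -> str:
    """Sample a relation type, avoiding labels already used on this pair."""
    for _ in range(16):
        lab = labels[int(rng.choice(len(labels), p=probs))]
        if lab not in used:
            return lab
    for lab in labels:  # deterministic fallback when the pair is nearly saturated
        if lab not in used:
            return lab
    raise RuntimeError("relation vocabulary exhausted for a single node pair")


def _star_edges(
    rng: np.random.Generator,
    focus: str,
    members: Sequence[str],
    n_edges: int,
    labels: list[str],
    probs: np.ndarray,
    exact: bool,
) -> list[Relation]:
    """One edge per member, then parallel extras up to *n_edges* total."""
    used: dict[str, set[str]] = {m: set() for m in members}
    edges: list[Relation] = []
    for m in members:
        lab = _sample_label(rng, labels, probs, used[m])
        used[m].add(lab)
        edges.append(Relation(source=focus, target=m, rel_type=lab))
    extra = n_edges - len(members)
    if extra > 0 and members:
        if exact:
            idx = [i % len(members) for i in range(extra)]
        else:
            idx = list(rng.integers(0, len(members), size=extra))
        for i in idx:
            m = members[i]
            lab = _sample_label(rng, labels, probs, used[m])
            used[m].add(lab)
            edges.append(Relation(source=focus, target=m, rel_type=lab))
    return edges


def _drug_quotas(edge_counts: Mapping[str, int], n_members: int) -> dict[str, int]:
    """Distinct-member quota per drug, proportional to its edge count."""
    names = sorted(edge_counts)
    total = sum(edge_counts.values())
    exact = {d: n_members * edge_counts[d] / total for d in names}
    quotas = {d: min(int(exact[d]), edge_counts[d]) for d in names}
    rest = n_members - sum(quotas.values())
    order = sorted(names, key=lambda d: (-(exact[d] - quotas[d]), d))
    i = 0
    while rest > 0:
        d = order[i % len(order)]
        if quotas[d] < edge_counts[d]:
            quotas[d] += 1
            rest -= 1
        i += 1
    return quotas


def write_gmt(sets: GeneSetCollection, path: str | Path) -> None:
    """Write gene sets in GMT, sorted for byte-stable output."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        for tid in sorted(sets.terms):
            name, members = sets.terms[tid]
            fh.write("\t".join([tid, name, *sorted(members)]) + "\n")


# ---------------------------------------------------------------- generator


def generate(params: GeneratorParams, out_dir: str | Path | None = None) -> GeneratedData:
    """Generate a knowledge graph, gene sets, mapping and ground truth.

    Deterministic for a fixed ``params.seed``. With *out_dir* the bundle
    is written as ``entities.tsv`` / ``relations.tsv`` / ``vocabulary.tsv``
    / ``go_bp.gmt`` / ``mapping.tsv`` / ``universe.txt`` / ``truth.json``.
    """
    params.validate()
    rng = np.random.default_rng(params.seed)
    labels = sorted(params.rel_type_weights)
    probs = np.array([params.rel_type_weights[l] for l in labels], dtype=float)
    probs = probs / probs.sum()
    reg_labels = sorted(set(labels) & set(REGULATORY_LABELS))
    if not reg_labels:
        reg_labels = sorted(REGULATORY_LABELS)

    g = KnowledgeGraph(vocabulary=default_vocabulary())

    genes = [f"g{i:05d}" for i in range(params.n_genes)]
    background = [f"b{i:05d}" for i in range(params.n_background_genes)]
    proteins = [f"p{i:05d}" for i in range(params.n_proteins)]
    disease = "disease:RA"

    for gid in genes + background:
        g.add_entity(Entity(id=gid, name=gid.upper(), entity_class="gene"))
    for pid in proteins:
        g.add_entity(Entity(id=pid, name=pid.upper(), entity_class="protein"))
    g.add_entity(Entity(id=disease, name="Rheumatoid arthritis", entity_class="disease"))

    drugs: dict[str, list[str]] = {}
    for group in sorted(params.drug_groups):
        drugs[group] = []
        for drug in sorted(params.drug_groups[group]):
            did = f"drug:{drug}"
            g.add_entity(Entity(id=did, name=drug, entity_class="drug"))
            drugs[group].append(did)

    # every protein codes for a gene; round-robin keeps drug-group protein
    # slices mapping inside their own gene slices
    mapping = {pid: genes[j % params.n_genes] for j, pid in enumerate(proteins)}

    # -- disease star
    disease_members = genes + proteins
    for rel in _star_edges(
        rng, disease, disease_members, params.disease_edges, labels, probs,
        params.exact_mode,
    ):
        g.add_relation(rel)

    # -- drug stars (members shared with the disease neighbourhood)
    slices = params.group_slices()
    for group in sorted(params.drug_groups):
        gene_rng, prot_rng = slices[group]
        union = [genes[i] for i in gene_rng] + [proteins[i] for i in prot_rng]
        edge_counts = {f"drug:{d}": e for d, e in params.drug_groups[group].items()}
        quotas = _drug_quotas(edge_counts, len(union))
        pos = 0
        extra_cursor = 0
        for did in sorted(edge_counts):
            share = union[pos:pos + quotas[did]]
            pos += quotas[did]
            # extras beyond the distinct-member quota become parallel edges /
            # attachments to members already claimed by other drugs
            n_extra = edge_counts[did] - quotas[did]
            members_for_drug = list(share)
            for _ in range(n_extra):
                members_for_drug.append(union[extra_cursor % len(union)])
                extra_cursor += 1
            used: dict[tuple[str, str], set[str]] = {}
            for m in members_for_drug:
                pair_used = used.setdefault((did, m), set())
                pair_used |= {
                    r.rel_type for r in g.relations_between(did, m)
                }
                lab = _sample_label(rng, labels, probs, pair_used)
                pair_used.add(lab)
                g.add_relation(Relation(source=did, target=m, rel_type=lab))

    # -- planted signed loops among member genes (taken from the tail of the
    #    gene list to stay clear of the drug-group slices)
    loop_records = []
    cursor = params.n_genes
    pol_label = {1: "expression upregulation", -1: "expression downregulation"}
    for spec in params.planted_loops:
        nodes = [genes[cursor - len(spec) + i] for i in range(len(spec))]
        cursor -= len(spec)
        for i, pol in enumerate(spec):
            src, tgt = nodes[i], nodes[(i + 1) % len(nodes)]
            g.add_relation(Relation(source=src, target=tgt, rel_type=pol_label[pol]))
        loop_records.append(
            {"nodes": nodes, "polarities": list(spec),
             "sign": int(np.prod(spec))}
        )

    # -- gene sets with planted enrichment, and the cascade planting
    universe = genes + background
    sets, truth_terms = _build_terms(params, rng, genes, background, slices)

    # process entities + regulation links driving the cascade
    term_ids = sorted(sets.terms)
    for tid in term_ids:
        g.add_entity(Entity(id=tid, name=sets.terms[tid][0], entity_class="process"))
    for tid in truth_terms["disease_regulated"]:
        lab = reg_labels[int(rng.integers(len(reg_labels)))]
        g.add_relation(Relation(source=disease, target=tid, rel_type=lab))
    all_drugs = [d for ds in drugs.values() for d in ds]
    for j, tid in enumerate(truth_terms["drug_regulated"]):
        did = all_drugs[j % len(all_drugs)] if all_drugs else None
        if did is None:
            break
        lab = reg_labels[int(rng.integers(len(reg_labels)))]
        g.add_relation(Relation(source=did, target=tid, rel_type=lab))
    # a few associative disease-process links that must NOT pass the
    # regulation filter
    for tid in truth_terms["disease_enriched"][
        params.planted_disease_regulated:params.planted_disease_regulated + 10
    ]:
        g.add_relation(Relation(source=disease, target=tid, rel_type="association"))

    truth = {
        "seed": params.seed,
        "disease": disease,
        "drug_groups": drugs,
        "universe_size": len(universe),
        "disease_query": genes,  # member genes plus mapped proteins collapse to this
        "group_queries": {
            name: [genes[i] for i in slices[name][0]] for name in sorted(slices)
        },
        "expected_cascade": {
            "significant_disease_terms": params.planted_enriched_terms,
            "disease_regulated": params.planted_disease_regulated,
            "after_drug_enriched_subtraction": params.planted_disease_regulated
            - params.planted_drug_enriched_overlap,
            "candidates": params.planted_disease_regulated
            - params.planted_drug_enriched_overlap
            - params.planted_drug_regulated,
        },
        "loops": loop_records,
        **truth_terms,
    }

    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = save_graph(g, out_dir)
        gmt_path = out_dir / "go_bp.gmt"
        write_gmt(sets, gmt_path)
        map_path = out_dir / "mapping.tsv"
        with open(map_path, "w") as fh:
            fh.write("protein_id\tgene_id\n")
            for pid in proteins:
                fh.write(f"{pid}\t{mapping[pid]}\n")
        uni_path = out_dir / "universe.txt"
        with open(uni_path, "w") as fh:
            fh.write("\n".join(universe) + "\n")
        truth_path = out_dir / "truth.json"
        with open(truth_path, "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
        paths.update(
            {"gmt": gmt_path, "mapping": map_path, "universe": uni_path,
             "truth": truth_path}
        )

    return GeneratedData(graph=g, sets=sets, mapping=mapping, truth=truth, paths=paths)


def _build_terms(
    params: GeneratorParams,
    rng: np.random.Generator,
    genes: list[str],
    background: list[str],
    slices: Mapping[str, tuple[range, range]],
) -> tuple[GeneSetCollection, dict]:
    """Construct the GMT terms and the cascade's term-level ground truth."""
    group_names = sorted(params.drug_groups)
    group_pools = {n: [genes[i] for i in slices[n][0]] for n in group_names}
    reserved = set().union(*group_pools.values()) if group_pools else set()
    disease_only = [g for g in genes if g not in reserved]
    shares = params.overlap_shares() if params.drug_groups else {}

    n_sig = params.planted_enriched_terms
    n_reg = params.planted_disease_regulated
    n_overlap = params.planted_drug_enriched_overlap
    n_drug_reg = params.planted_drug_regulated

    # pool assignment per term index:
    #   [0, n_overlap)                      -> drug-group pools (overlap terms)
    #   [n_overlap, n_reg)                  -> disease-only pool (survivors)
    #   [n_reg, n_reg + drug extras)        -> drug-group pools (drug-only sig)
    #   [.., n_sig)                         -> disease-only pool
    #   [n_sig, n_terms)                    -> background pool (null terms)
    pool_of: list[list[str]] = []
    term_group: list[str | None] = []
    for name in group_names:
        for _ in range(shares.get(name, 0)):
            pool_of.append(group_pools[name])
            term_group.append(name)
    while len(pool_of) < n_reg:
        pool_of.append(disease_only)
        term_group.append(None)
    for name in group_names:
        for _ in range(params.drug_sig_counts.get(name, 0) - shares.get(name, 0)):
            pool_of.append(group_pools[name])
            term_group.append(name)
    while len(pool_of) < n_sig:
        pool_of.append(disease_only)
        term_group.append(None)
    while len(pool_of) < params.n_terms:
        pool_of.append(background)
        term_group.append("null")

    terms: dict[str, tuple[str, frozenset[str]]] = {}
    universe = frozenset(genes) | frozenset(background)
    all_gene_arr = np.array(genes + background)
    term_ids = [f"GO:{i + 1:07d}" for i in range(params.n_terms)]
    for i, tid in enumerate(term_ids):
        pool = pool_of[i]
        size = min(params.term_size, len(pool))
        if params.exact_mode or term_group[i] == "null":
            chosen = rng.choice(len(pool), size=size, replace=False)
            members = frozenset(pool[j] for j in chosen)
        else:
            # stochastic planting: a fraction of the term comes from its pool
            # (the query, for planted terms), the rest from anywhere
            n_in = int(round(params.planted_effect * size))
            chosen = rng.choice(len(pool), size=n_in, replace=False)
            members = {pool[j] for j in chosen}
            while len(members) < size:
                members.add(str(rng.choice(all_gene_arr)))
            members = frozenset(members)
        terms[tid] = (f"synthetic biological process {i + 1}", members)

    sig_ids = term_ids[:n_sig]
    regulated = term_ids[:n_reg]
    overlap = term_ids[:n_overlap]
    survivors = term_ids[n_overlap:n_reg]
    drug_regulated = survivors[:n_drug_reg]
    candidates = survivors[n_drug_reg:]
    drug_sig: dict[str, list[str]] = {n: [] for n in group_names}
    for i, grp in enumerate(term_group):
        if grp in drug_sig:
            drug_sig[grp].append(term_ids[i])

    truth_terms = {
        "disease_enriched": sig_ids,
        "disease_regulated": regulated,
        "drug_enriched_overlap": overlap,
        "drug_significant": drug_sig,
        "drug_regulated": drug_regulated,
        "candidates": candidates,
        "null_terms": term_ids[n_sig:],
    }
    return GeneSetCollection(terms=terms, universe=universe), truth_terms


# ------------------------------------------------- cytokine/Wnt mechanism


def generate_wnt_loop_fixture(out_dir: str | Path | None = None) -> GeneratedData:
    """Cytokine/Wnt mechanism fixture with one planted positive loop.

    Encodes the prose-level mechanism around the non-canonical Wnt
    pathway in rheumatoid arthritis: the proinflammatory cytokines IL1B,
    TNF and IL6 activate expression of WNT5A; WNT5A in turn activates
    IL1B expression (the positive feedback loop); TNF and IL1B activate
    DKK1, which inhibits the canonical Wnt signalling process.
    """
    g = KnowledgeGraph(vocabulary=default_vocabulary())
    for gid, name in [
        ("IL1B", "interleukin-1 beta"),
        ("TNF", "tumor necrosis factor alpha"),
        ("IL6", "interleukin-6"),
        ("WNT5A", "WNT5A"),
        ("DKK1", "Dickkopf-1"),
    ]:
        g.add_entity(Entity(id=gid, name=name, entity_class="gene"))
    g.add_entity(
        Entity(id="GO:0060070", name="canonical Wnt signaling pathway",
               entity_class="process")
    )
    up = "expression upregulation"
    for src, tgt in [
        ("IL1B", "WNT5A"), ("TNF", "WNT5A"), ("IL6", "WNT5A"),
        ("WNT5A", "IL1B"), ("TNF", "DKK1"), ("IL1B", "DKK1"),
    ]:
        g.add_relation(Relation(source=src, target=tgt, rel_type=up))
    g.add_relation(
        Relation(source="DKK1", target="GO:0060070", rel_type="negative regulation")
    )

    sets = GeneSetCollection(
        terms={"GO:0060070": ("canonical Wnt signaling pathway",
                              frozenset({"WNT5A", "DKK1"}))},
        universe=frozenset({"IL1B", "TNF", "IL6", "WNT5A", "DKK1"}),
    )
    truth = {
        "positive_loops": [["IL1B", "WNT5A"]],
        "negative_loops": [],
        "activations": [["IL1B", "WNT5A"], ["TNF", "WNT5A"], ["IL6", "WNT5A"],
                        ["WNT5A", "IL1B"], ["TNF", "DKK1"], ["IL1B", "DKK1"]],
    }
    paths = None
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = save_graph(g, out_dir)
        with open(out_dir / "truth.json", "w") as fh:
            json.dump(truth, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return GeneratedData(graph=g, sets=sets, mapping={}, truth=truth, paths=paths)
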