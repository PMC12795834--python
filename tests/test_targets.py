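"""The staged target-process cascade and its stage operations."""

import math
import random

import numpy as np
import pytest

from agnet.enrichment import EnrichmentResult, enrich
from agnet.graph import Entity, KnowledgeGraph, LookupGraphError, Relation
from agnet.synthetic import default_vocabulary, generate, small_params
from agnet.targets import (
    CascadeConfig,
    CascadeStageError,
    filter_disease_regulated,
    resolve_regulation_labels,
    run_cascade,
    subtract_drug_enriched,
    subtract_drug_regulated,
)


def _result(tid, p_adj=1e-6, significant=True):
    return EnrichmentResult(
        term_id=tid, term_name=tid, k=5, n=50, K=10, N=1000,
        p_raw=p_adj / 10, p_adj=p_adj, significant=significant,
    )


def _cfg(groups=None, **kw):
    return CascadeConfig(drug_groups=groups or {"grp": ["drug:x"]}, **kw)


def _graph_with_processes(n_terms=6):
    g = KnowledgeGraph(vocabulary=default_vocabulary())
    g.add_entity(Entity(id="dis", name="dis", entity_class="disease"))
    g.add_entity(Entity(id="drug:x", name="x", entity_class="drug"))
    for i in range(n_terms):
        tid = f"GO:{i + 1:07d}"
        g.add_entity(Entity(id=tid, name=tid, entity_class="process"))
    return g


class TestRegulationLabelResolution:
    def test_aliases_expand_case_insensitively(self):
        g = KnowledgeGraph(vocabulary=default_vocabulary())
        labels = resolve_regulation_labels(_cfg(), g)
        # the coarse filter Regulation/Downregulation/Upregulation covers all
        # nine regulatory labels through the alias table, and nothing else
        assert labels == {
            t.label for t in g.vocabulary.values() if t.category == "regulatory"
        }

    def test_restricting_the_filter_restricts_the_labels(self):
        g = KnowledgeGraph(vocabulary=default_vocabulary())
        labels = resolve_regulation_labels(
            _cfg(regulation_types=frozenset({"Upregulation"})), g
        )
        assert labels == {
            "expression upregulation", "activity upregulation", "positive regulation"
        }


class TestFilterDiseaseRegulated:
    def test_no_process_relations_gives_empty(self):
        g = _graph_with_processes()
        out = filter_disease_regulated([_result("GO:0000001")], g, "dis", _cfg())
        assert out == []

    def test_planted_regulated_terms_are_selected(self, small_bundle):
        g = small_bundle.graph
        truth = small_bundle.truth
        sig = [_result(t) for t in truth["disease_enriched"]]
        cfg = _cfg({k: v for k, v in truth["drug_groups"].items()})
        out = filter_disease_regulated(sig, g, truth["disease"], cfg)
        assert out == truth["disease_regulated"]

    def test_associative_links_do_not_pass_the_filter(self, small_bundle):
        """Disease-process 'association' edges exist but are not regulation."""
        g = small_bundle.graph
        truth = small_bundle.truth
        assoc_terms = truth["disease_enriched"][len(truth["disease_regulated"]):]
        has_assoc = [
            t for t in assoc_terms
            if any(r.rel_type == "association" for r in g.relations_between(truth["disease"], t))
        ]
        assert has_assoc, "fixture should plant associative disease-process links"
        out = filter_disease_regulated(
            [_result(t) for t in has_assoc], g, truth["disease"],
            _cfg({k: v for k, v in truth["drug_groups"].items()}),
        )
        assert out == []

    def test_term_without_process_node_warns_and_drops(self):
        g = _graph_with_processes(1)
        with pytest.warns(UserWarning, match="GO:0009999"):
            out = filter_disease_regulated([_result("GO:0009999")], g, "dis", _cfg())
        assert out == []

    def test_unknown_disease_raises(self):
        g = _graph_with_processes()
        with pytest.raises(LookupGraphError):
            filter_disease_regulated([], g, "missing", _cfg())

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_relation_table_scan(self, seed):
        rng = np.random.default_rng(seed)
        g = _graph_with_processes(12)
        reg = sorted(
            t.label for t in g.vocabulary.values() if t.category == "regulatory"
        )
        planted = set()
        for i in range(12):
            tid = f"GO:{i + 1:07d}"
            if rng.random() < 0.5:
                lab = reg[int(rng.integers(len(reg)))] if rng.random() < 0.6 else "association"
                g.add_relation(Relation(source="dis", target=tid, rel_type=lab))
                if lab != "association":
                    planted.add(tid)
        sig = [_result(f"GO:{i + 1:07d}") for i in range(12)]
        out = filter_disease_regulated(sig, g, "dis", _cfg())
        expected = [
            t.term_id for t in sig
            if any(
                r.rel_type in reg and {r.source, r.target} == {"dis", t.term_id}
                for r in g.relations
            )
        ]
        assert out == expected and set(out) == planted


class TestSubtractDrugEnriched:
    def test_empty_enrichments_are_identity(self):
        terms = ["GO:0000003", "GO:0000001"]
        assert subtract_drug_enriched(terms, {"grp": []}) == terms

    def test_union_subtraction_preserves_order(self):
        terms = [f"GO:{i:07d}" for i in range(1, 8)]
        drug = {
            "a": [_result("GO:0000002"), _result("GO:0000009")],
            "b": [_result("GO:0000005", p_adj=0.9, significant=False),
                  _result("GO:0000006")],
        }
        out = subtract_drug_enriched(terms, drug, alpha=0.05)
        # GO:0000005 is not significant at alpha and must survive
        assert out == ["GO:0000001", "GO:0000003", "GO:0000004", "GO:0000005",
                       "GO:0000007"]

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_independent_set_difference(self, seed):
        rng = random.Random(seed)
        terms = [f"GO:{i:07d}" for i in range(1, 40)]
        disease = rng.sample(terms, 20)
        drug = {
            "g1": [_result(t) for t in rng.sample(terms, 10)],
            "g2": [_result(t) for t in rng.sample(terms, 8)],
        }
        expected_removed = {r.term_id for rs in drug.values() for r in rs}
        out = subtract_drug_enriched(disease, drug)
        assert out == [t for t in disease if t not in expected_removed]


class TestSubtractDrugRegulated:
    def test_no_drug_relations_all_candidates(self):
        g = _graph_with_processes(3)
        out = subtract_drug_regulated([f"GO:{i:07d}" for i in (1, 2, 3)], g, _cfg())
        assert all(c.status == "candidate" for c in out)
        assert math.isnan(out[0].p_adj_disease)  # standalone call lacks enrichment

    def test_regulated_terms_are_excluded(self):
        g = _graph_with_processes(3)
        g.add_relation(Relation(source="drug:x", target="GO:0000002",
                                rel_type="expression downregulation"))
        g.add_relation(Relation(source="drug:x", target="GO:0000003",
                                rel_type="association"))  # not a regulation type
        out = subtract_drug_regulated([f"GO:{i:07d}" for i in (1, 2, 3)], g, _cfg())
        status = {c.term_id: c.status for c in out}
        assert status == {
            "GO:0000001": "candidate",
            "GO:0000002": "excluded_drug_regulated",
            "GO:0000003": "candidate",
        }

    def test_unknown_drug_raises(self):
        g = _graph_with_processes(1)
        with pytest.raises(LookupGraphError):
            subtract_drug_regulated(["GO:0000001"], g, _cfg({"grp": ["drug:ghost"]}))


class TestRunCascade:
    def _cfg_for(self, bundle, **kw):
        return CascadeConfig(
            drug_groups={k: list(v) for k, v in bundle.truth["drug_groups"].items()},
            **kw,
        )

    def test_planted_counts_reproduced(self, small_bundle):
        report = run_cascade(
            small_bundle.graph, small_bundle.truth["disease"], small_bundle.sets,
            self._cfg_for(small_bundle), small_bundle.mapping,
        )
        expected = small_bundle.truth["expected_cascade"]
        for stage, count in expected.items():
            assert report.stage_counts[stage] == count
        assert sorted(c.term_id for c in report.candidates) == sorted(
            small_bundle.truth["candidates"]
        )

    def test_conservation_of_statuses(self, small_bundle):
        report = run_cascade(
            small_bundle.graph, small_bundle.truth["disease"], small_bundle.sets,
            self._cfg_for(small_bundle), small_bundle.mapping,
        )
        assert len(report.table) == report.stage_counts["significant_disease_terms"]
        by_status = {}
        for c in report.table:
            by_status[c.status] = by_status.get(c.status, 0) + 1
        assert sum(by_status.values()) == len(report.table)
        assert by_status.get("candidate", 0) == report.stage_counts["candidates"]
        # every candidate satisfies the defining boolean conjunction
        for c in report.candidates:
            assert c.disease_regulated and not c.drug_enriched and not c.drug_regulated
            assert c.p_adj_disease < 0.05

    @pytest.mark.parametrize("seed", range(10))
    def test_composition_equals_manual_stages(self, seed):
        """End-to-end run equals calling the four stages by hand."""
        bundle = generate(small_params(seed=seed))
        g, truth = bundle.graph, bundle.truth
        cfg = self._cfg_for(bundle)
        report = run_cascade(g, truth["disease"], bundle.sets, cfg, bundle.mapping)

        from agnet.agn import member_gene_list, reconstruct_agn

        disease_genes = member_gene_list(
            reconstruct_agn(g, [truth["disease"]]), g, bundle.mapping
        )
        disease_enr = enrich(disease_genes, bundle.sets, cfg.alpha, cfg.min_overlap)
        drug_enr = {
            name: enrich(
                member_gene_list(reconstruct_agn(g, drugs), g, bundle.mapping),
                bundle.sets, cfg.alpha, cfg.min_overlap,
            )
            for name, drugs in cfg.drug_groups.items()
        }
        sig = [r for r in disease_enr if r.significant]
        regulated = filter_disease_regulated(sig, g, truth["disease"], cfg)
        surviving = subtract_drug_enriched(regulated, drug_enr, cfg.alpha)
        classified = subtract_drug_regulated(surviving, g, cfg)
        manual_candidates = sorted(
            c.term_id for c in classified if c.status == "candidate"
        )
        assert sorted(c.term_id for c in report.candidates) == manual_candidates
        assert report.stage_counts["significant_disease_terms"] == len(sig)
        assert report.stage_counts["disease_regulated"] == len(regulated)
        assert report.stage_counts["after_drug_enriched_subtraction"] == len(surviving)

    def test_term_order_is_immaterial(self, small_bundle):
        g, truth = small_bundle.graph, small_bundle.truth
        cfg = self._cfg_for(small_bundle)
        sig = [_result(t) for t in truth["disease_enriched"]]
        shuffled = list(sig)
        random.Random(9).shuffle(shuffled)
        a = set(filter_disease_regulated(sig, g, truth["disease"], cfg))
        b = set(filter_disease_regulated(shuffled, g, truth["disease"], cfg))
        assert a == b
        drug_enr = {"grp": [_result(t) for t in truth["drug_enriched_overlap"]]}
        terms = truth["disease_regulated"]
        sh_terms = list(terms)
        random.Random(9).shuffle(sh_terms)
        assert set(subtract_drug_enriched(terms, drug_enr)) == set(
            subtract_drug_enriched(sh_terms, drug_enr)
        )

    def test_adding_drug_regulation_edge_never_adds_candidates(self, small_bundle):
        import copy

        g, truth = small_bundle.graph, small_bundle.truth
        cfg = self._cfg_for(small_bundle)
        base = run_cascade(g, truth["disease"], small_bundle.sets, cfg, small_bundle.mapping)
        g2 = g.subgraph(set(g.entities))  # deep-ish copy via induced full subgraph
        victim = base.candidates[0].term_id
        drug = next(iter(cfg.drug_groups.values()))[0]
        g2.add_relation(Relation(source=drug, target=victim, rel_type="regulation"))
        after = run_cascade(g2, truth["disease"], small_bundle.sets, cfg, small_bundle.mapping)
        assert after.stage_counts["candidates"] == base.stage_counts["candidates"] - 1

    def test_error_is_attributed_to_its_stage(self):
        g = KnowledgeGraph(vocabulary=default_vocabulary())
        g.add_entity(Entity(id="dis", name="dis", entity_class="disease"))
        g.add_entity(Entity(id="drug:x", name="x", entity_class="drug"))
        from agnet.enrichment import GeneSetCollection

        sets = GeneSetCollection(
            terms={"GO:0000001": ("t", frozenset({"gA"}))}, universe=frozenset({"gA"})
        )
        with pytest.raises(CascadeStageError, match=r"\[stage: enrichment\]"):
            run_cascade(g, "dis", sets, _cfg(), {})


def test_cascade_config_validation():
    with pytest.raises(ValueError, match="drug_groups"):
        CascadeConfig(drug_groups={})
    with pytest.raises(ValueError, match="alpha"):
        CascadeConfig(drug_groups={"g": ["d"]}, alpha=1.5)
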