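"""Contact maps, duplicate-rule detection, consistency checking."""

import pytest
from rdflib import Graph, OWL, RDF, RDFS, URIRef

from rbmannot import analyses, fixtures
from rbmannot.analyses import (Conflict, ContactEdge, DuplicatePair,
                               check_consistency, contact_map, expand_sameas,
                               find_conflicts, find_duplicate_rules,
                               merged_graph, render_contact_dot,
                               render_conflicts)
from rbmannot.annotations import annotation_graph
from rbmannot.kappa import parse_model
from rbmannot.materialize import materialize_model
from rbmannot.vocab import BQBIOL, RBMO

from conftest import brute_force_contact_edges, brute_force_duplicates

BASE = "http://example.org/m#"
MV = "http://example.org/mockvocab#"


def edge_key(edges):
    return {(e.endpoint_a, e.endpoint_b, e.rules) for e in edges}


class TestContactMap:
    def test_dimer_rule_single_self_edge(self):
        text = (f"#^ @prefix : <{BASE}> .\n"
                "'dimer' A(site1~v,site2~z),A(site1~v,site2~y) -> "
                "A(site1~v,site2~z!1),A(site1~v,site2~y!1) @ kf\n")
        model = parse_model(text)
        edges = contact_map(materialize_model(model))
        assert len(edges) == 1
        (e,) = edges
        assert e.endpoint_a == (BASE + "A", BASE + "A:site2")
        assert e.endpoint_b == (BASE + "A", BASE + "A:site2")
        assert e.rules == frozenset({BASE + "dimer"})

    def test_model_without_bonds_gives_empty_map(self):
        text = (f"#^ @prefix : <{BASE}> .\n"
                "'r' A(s~u) -> A(s~v) @ k\n")
        assert contact_map(materialize_model(parse_model(text))) == set()

    def test_non_materialized_graph_rejected(self):
        with pytest.raises(ValueError):
            contact_map(Graph())

    def test_tcs_equals_brute_force_and_has_dna_binding_edge(
            self, tcs_model_parsed, tcs_graph):
        edges = contact_map(tcs_graph)
        oracle = brute_force_contact_edges(tcs_model_parsed,
                                           fixtures.tcs_base())
        assert edge_key(edges) == oracle
        base = fixtures.tcs_base()
        assert any({e.endpoint_a[0], e.endpoint_b[0]} ==
                   {base + "Spo0A", base + "Op"} for e in edges)

    def test_lhs_only_bond_still_witnesses_contact(self):
        text = (f"#^ @prefix : <{BASE}> .\n"
                "'unbind' A(s!1),B(t!1) -> A(s),B(t) @ k\n")
        edges = contact_map(materialize_model(parse_model(text)))
        assert len(edges) == 1

    @pytest.mark.parametrize("seed", range(25))
    def test_equals_brute_force_on_random_models(self, seed):
        cfg = fixtures.GeneratorConfig(seed=seed)
        model = parse_model(fixtures.random_model(cfg))
        g = materialize_model(model)
        assert edge_key(contact_map(g)) == \
            brute_force_contact_edges(model, fixtures.random_base(cfg))


class TestContactDot:
    def test_empty_edge_set_valid_dot(self):
        dot = render_contact_dot(set())
        assert dot.startswith("graph contact_map {") and dot.rstrip().endswith("}")

    def test_edge_without_annotations_names_sites(self):
        e = ContactEdge((BASE + "A", BASE + "A:s1"),
                        (BASE + "B", BASE + "B:s2"),
                        frozenset({BASE + "r"}))
        dot = render_contact_dot({e})
        assert "s1" in dot and "s2" in dot and '"A"' in dot and '"B"' in dot

    def test_tcs_dot_contains_uniprot_identifier(self, tcs_graph):
        dot = render_contact_dot(contact_map(tcs_graph), tcs_graph)
        assert "P16497" in dot  # kinase annotation pulled into the node

    def test_edge_label_carries_witness_rules(self, tcs_graph):
        dot = render_contact_dot(contact_map(tcs_graph), tcs_graph)
        assert "TF_binding" in dot


class TestDuplicates:
    def annotated(self, *rule_terms):
        lines = [f"#^ @prefix : <{BASE}> .",
                 "#^ @prefix rbmo: <http://purl.org/rbm/rbmo#> .",
                 "#^ @prefix rdf: "
                 "<http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
                 "#^ @prefix bqbiol: "
                 "<http://biomodels.net/biology-qualifiers/> ."]
        body = []
        for i, terms in enumerate(rule_terms):
            lines.append(f"#^ :r{i} rdf:type rbmo:Rule .")
            for t in terms:
                lines.append(f"#^ :r{i} bqbiol:is <{t}> .")
            body.append(f"'r{i}' A(s) -> A(s) @ k")
        return materialize_model(parse_model("\n".join(lines + body) + "\n"))

    def test_shared_identity_detected(self):
        kegg = "http://identifiers.org/kegg.reaction/R00299"
        g = self.annotated([kegg], [kegg])
        (pair,) = find_duplicate_rules(g)
        assert pair.rule_a == BASE + "r0" and pair.rule_b == BASE + "r1"
        assert pair.shared == frozenset({kegg})

    def test_single_rule_never_self_pairs(self):
        g = self.annotated(["http://x/1"])
        assert find_duplicate_rules(g) == set()

    def test_disjoint_identities_no_pair(self):
        g = self.annotated(["http://x/1"], ["http://x/2"])
        assert find_duplicate_rules(g) == set()

    def test_pair_ordering_invariant(self):
        with pytest.raises(ValueError):
            DuplicatePair("b", "a", frozenset({"x"}))
        with pytest.raises(ValueError):
            DuplicatePair("a", "b", frozenset())

    @pytest.mark.parametrize("seed", range(10))
    def test_equals_brute_force_on_random_models(self, seed):
        cfg = fixtures.GeneratorConfig(seed=seed, plant_duplicate=True)
        g = materialize_model(parse_model(fixtures.random_model(cfg)))
        identities = {}
        for r in g.subjects(RDF.type, RBMO.Rule):
            objs = {str(o) for o in g.objects(r, BQBIOL["is"])}
            if objs:
                identities[str(r)] = objs
        assert {(p.rule_a, p.rule_b, p.shared)
                for p in find_duplicate_rules(g)} == \
            brute_force_duplicates(identities)

    def test_planted_duplicate_is_the_only_pair(self):
        cfg = fixtures.GeneratorConfig(seed=11, plant_duplicate=True)
        g = materialize_model(parse_model(fixtures.random_model(cfg)))
        pairs = find_duplicate_rules(g)
        assert len(pairs) == 1
        (p,) = pairs
        base = fixtures.random_base(cfg)
        assert {p.rule_a, p.rule_b} == {base + "r0", base + "r1"}


class TestSameAs:
    def test_adds_one_triple_per_bqbiol_is(self):
        g = Graph()
        g.add((URIRef("http://x/a"), BQBIOL["is"], URIRef("http://x/T")))
        out = expand_sameas(g)
        assert len(out) == 2
        assert (URIRef("http://x/a"), OWL.sameAs, URIRef("http://x/T")) in out
        assert len(g) == 1  # input untouched

    def test_no_bqbiol_is_identical_graph(self):
        g = Graph()
        g.add((URIRef("http://x/a"), RDF.type, URIRef("http://x/T")))
        assert set(expand_sameas(g)) == set(g)

    def test_tcs_added_count_equals_is_count(self, tcs_text):
        g = annotation_graph(tcs_text)
        n_is = len(list(g.subject_objects(BQBIOL["is"])))
        assert len(expand_sameas(g)) == len(g) + n_is


class TestConflicts:
    def triples(self, *rows):
        g = Graph()
        for s, p, o in rows:
            g.add((URIRef(s), p, URIRef(o)))
        return g

    def test_direct_disjoint_types_conflict(self):
        g = self.triples(
            ("http://x/x", RDF.type, "http://x/A"),
            ("http://x/x", RDF.type, "http://x/B"),
            ("http://x/A", OWL.disjointWith, "http://x/B"))
        (c,) = find_conflicts(g)
        assert c.entity == "http://x/x"
        assert {c.class_a, c.class_b} == {"http://x/A", "http://x/B"}
        assert all(t in g for t in c.chain)

    def test_empty_graph_no_conflicts(self):
        assert find_conflicts(Graph()) == []

    def test_sameas_and_subclass_hop(self):
        g = self.triples(
            ("http://x/x", OWL.sameAs, "http://x/a"),
            ("http://x/a", RDF.type, "http://x/SubA"),
            ("http://x/x", RDF.type, "http://x/B"),
            ("http://x/SubA", RDFS.subClassOf, "http://x/A"),
            ("http://x/A", OWL.disjointWith, "http://x/B"))
        (c,) = find_conflicts(g)
        chain = set(c.chain)
        assert (URIRef("http://x/x"), OWL.sameAs, URIRef("http://x/a")) in chain
        assert (URIRef("http://x/SubA"), RDFS.subClassOf,
                URIRef("http://x/A")) in chain
        assert all(t in g for t in c.chain)

    def test_exhaustive_oracle_on_random_type_pairs(self):
        # brute force: all pooled type pairs of every sameAs class
        g = self.triples(
            ("http://x/p", OWL.sameAs, "http://x/q"),
            ("http://x/q", OWL.sameAs, "http://x/r"),
            ("http://x/p", RDF.type, "http://x/T1"),
            ("http://x/r", RDF.type, "http://x/T2"),
            ("http://x/s", RDF.type, "http://x/T3"),
            ("http://x/T1", OWL.disjointWith, "http://x/T2"),
            ("http://x/T3", OWL.disjointWith, "http://x/T1"))
        conflicts = find_conflicts(g)
        # {p,q,r} pools T1,T2 (disjoint) -> 1 conflict; s alone with T3: none
        assert len(conflicts) == 1
        assert {conflicts[0].class_a, conflicts[0].class_b} == \
            {"http://x/T1", "http://x/T2"}

    def test_conflict_free_fixture_reports_none(self, mock_ontology_graph):
        cfg = fixtures.GeneratorConfig(seed=5)
        g = materialize_model(parse_model(fixtures.random_model(cfg)))
        assert check_consistency(g, [mock_ontology_graph]) == []

    def test_planted_conflict_found_with_replayable_chain(
            self, mock_ontology_graph):
        cfg = fixtures.GeneratorConfig(seed=5, plant_conflict=True)
        g = materialize_model(parse_model(fixtures.random_model(cfg)))
        conflicts = check_consistency(g, [mock_ontology_graph])
        assert len(conflicts) >= 1
        merged = merged_graph(g, [mock_ontology_graph])
        for c in conflicts:
            assert all(t in merged for t in c.chain)
        assert any({c.class_a, c.class_b} == {MV + "SubA", MV + "ClassB"}
                   for c in conflicts)

    def test_report_rendering(self):
        g = self.triples(
            ("http://x/x", RDF.type, "http://x/A"),
            ("http://x/x", RDF.type, "http://x/B"),
            ("http://x/A", OWL.disjointWith, "http://x/B"))
        text = render_conflicts(find_conflicts(g))
        assert "conflict 1" in text and "  1. " in text
        assert render_conflicts([]) == "no conflicts found\n"
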