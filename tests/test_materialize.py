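"""RDF materialization of rules and pattern normalization."""

from collections import Counter

import pytest
from rdflib import Graph, RDF, URIRef

from rbmannot import fixtures, kappa
from rbmannot.annotations import annotation_graph
from rbmannot.kappa import parse_model
from rbmannot.materialize import (NormalizationError, bond_uri,
                                  materialize_model, normalize_patterns)
from rbmannot.naming import PrefixedName
from rbmannot.vocab import DCT, RBMO

BASE = "http://example.org/m#"


def U(local: str) -> URIRef:
    return URIRef(BASE + local)


class TestMaterializeModel:
    def test_cooperative_unbinding_status_nodes(self, tcs_graph):
        """LHS Spo0A(DNAb!1,RR~p): DNAb bound via a bond URI, RR carries the
        phosphorylated internal state and is unbound."""
        base = fixtures.tcs_base()
        dnab = URIRef(base + "Cooperative_unbinding:lhs:1:DNAb")
        rr = URIRef(base + "Cooperative_unbinding:lhs:1:RR")
        assert (dnab, RBMO.status, RBMO.BoundState) in tcs_graph
        assert (dnab, RBMO.isStatusOf, URIRef(base + "Spo0A:DNAb")) in tcs_graph
        bonds = list(tcs_graph.objects(dnab, RBMO.isBoundBy))
        assert len(bonds) == 1
        assert (rr, RBMO.internalState,
                URIRef(base + "Spo0A:RR:p")) in tcs_graph
        assert (rr, RBMO.status, RBMO.UnboundState) in tcs_graph
        assert (rr, RBMO.isBoundBy, None) not in tcs_graph

    def test_empty_lhs_pattern_has_no_agents(self):
        text = (f"#^ @prefix : <{BASE}> .\n"
                "'mk' -> A(s) @ k\n")
        g = materialize_model(parse_model(text))
        lhs = U("mk:lhs")
        assert (U("mk"), RBMO.lhs, lhs) in g
        assert (lhs, RDF.type, RBMO.Pattern) in g
        assert list(g.objects(lhs, RBMO.agent)) == []

    def test_every_bond_has_exactly_two_endpoints(self, tcs_graph,
                                                  tcs_model_parsed):
        counts = Counter(b for _, b in tcs_graph.subject_objects(RBMO.isBoundBy))
        assert counts and all(n == 2 for n in counts.values())
        # oracle: count bond-label occurrences in the parsed rules
        expected_bonds = sum(
            len(set(side.bond_labels()))
            for r in tcs_model_parsed.rules for side in (r.lhs, r.rhs))
        assert len(counts) == expected_bonds

    def test_author_annotations_conserved(self, tcs_text, tcs_graph):
        authored = annotation_graph(tcs_text)
        for t in authored:
            assert t in tcs_graph

    def test_declaration_chain_agent_site_state(self, tcs_graph):
        base = fixtures.tcs_base()
        a, s, st = (URIRef(base + "Spo0A"), URIRef(base + "Spo0A:RR"),
                    URIRef(base + "Spo0A:RR:p"))
        assert (a, RDF.type, RBMO.Agent) in tcs_graph
        assert (a, RBMO.hasSite, s) in tcs_graph
        assert (s, RBMO.hasState, st) in tcs_graph
        assert (s, RBMO.siteOf, a) in tcs_graph
        assert (st, RBMO.stateOf, s) in tcs_graph

    def test_subrule_links(self, tcs_graph):
        base = fixtures.tcs_base()
        r, sr = URIRef(base + "Phos"), URIRef(base + "Phos:1")
        assert (r, RBMO.hasSubrule, sr) in tcs_graph
        assert (sr, RBMO.subruleOf, r) in tcs_graph
        assert (sr, RDF.type, RBMO.Rule) in tcs_graph
        # token transformation materialized as the subrule's patterns
        assert (URIRef(base + "Phos:1:lhs"), RBMO.agent,
                URIRef(base + "ATP")) in tcs_graph
        assert (URIRef(base + "Phos:1:rhs"), RBMO.agent,
                URIRef(base + "ADP")) in tcs_graph

    def test_observable_pattern_linked(self, tcs_graph):
        base = fixtures.tcs_base()
        obs = URIRef(base + "Spo0A_p")
        assert (obs, RDF.type, RBMO.Observable) in tcs_graph
        pat = tcs_graph.value(obs, RBMO.pattern)
        assert pat is not None
        assert (pat, RDF.type, RBMO.Pattern) in tcs_graph

    def test_bound_unknown_has_boundstate_but_no_bond(self):
        text = (f"#^ @prefix : <{BASE}> .\n"
                "'r' A(s!_) -> A(s) @ k\n")
        g = materialize_model(parse_model(text))
        st = U("r:lhs:1:s")
        assert (st, RBMO.status, RBMO.BoundState) in g
        assert g.value(st, RBMO.isBoundBy) is None

    def test_unspecified_binding_emits_no_status(self):
        text = (f"#^ @prefix : <{BASE}> .\n"
                "'r' A(s?) -> A(s?) @ k\n")
        g = materialize_model(parse_model(text))
        assert g.value(U("r:lhs:1:s"), RBMO.status) is None

    def test_unlabeled_rule_skipped_with_warning(self):
        m = parse_model("%agent: A(s)")
        m.rules.append(kappa.Rule(None, kappa.parse_pattern("A(s)"),
                                  kappa.parse_pattern("A(s)"), "k"))
        with pytest.warns(UserWarning, match="unlabeled"):
            g = materialize_model(m, base=BASE)
        assert not list(g.subjects(RDF.type, RBMO.Rule))

    def test_missing_base_everywhere_raises(self):
        from rbmannot.annotations import MissingEmptyPrefixError
        with pytest.raises(MissingEmptyPrefixError):
            materialize_model(parse_model("%agent: A(s)"))

    @pytest.mark.parametrize("seed", range(25))
    def test_status_and_bond_invariants_random(self, seed):
        """Every status node has exactly one isStatusOf; every bond exactly
        two isBoundBy referents."""
        text = fixtures.random_model(fixtures.GeneratorConfig(seed=seed))
        g = materialize_model(parse_model(text))
        status_counts = Counter(
            s for s, _ in g.subject_objects(RBMO.isStatusOf))
        assert all(n == 1 for n in status_counts.values())
        bond_counts = Counter(b for _, b in g.subject_objects(RBMO.isBoundBy))
        assert all(n == 2 for n in bond_counts.values())


class TestBondUri:
    def test_sides_distinct(self):
        assert bond_uri(":dimer", "lhs", 1) != bond_uri(":dimer", "rhs", 1)

    def test_deterministic(self):
        assert bond_uri(":dimer", "rhs", 1) == bond_uri(":dimer", "rhs", 1)

    def test_rules_distinct(self):
        assert bond_uri(":a", "lhs", 1) != bond_uri(":b", "lhs", 1)

    def test_labels_distinct_and_prefixedname_accepted(self):
        pn = PrefixedName("", "r")
        assert bond_uri(pn, "lhs", 1, BASE) != bond_uri(pn, "lhs", 2, BASE)
        assert bond_uri(pn, "lhs", 1, BASE).startswith(BASE)

    def test_invalid_label_rejected(self):
        with pytest.raises(ValueError):
            bond_uri(":r", "lhs", 0)


class TestNormalize:
    DECL = "%agent: A(site1~u~v,site2~x~y~z)\n"

    def test_sites_reordered_to_declaration_order(self):
        m = parse_model(self.DECL + "'r' A(site2~y,site1~u) -> "
                        "A(site2~y,site1~v) @ k\n")
        n = normalize_patterns(m)
        ap = n.rules[0].lhs.agents[0]
        assert [sp.site_name for sp in ap.sites] == ["site1", "site2"]
        assert [sp.state for sp in ap.sites] == ["u", "y"]

    def test_idempotent(self):
        m = parse_model(self.DECL + "'r' A(site2~y,site1~u) -> "
                        "A(site1~u,site2~x) @ k\n")
        once = normalize_patterns(m)
        assert normalize_patterns(once) == once

    def test_already_normal_unchanged(self):
        m = parse_model(self.DECL + "'r' A(site1~u,site2~y) -> "
                        "A(site1~v,site2~y) @ k\n")
        assert normalize_patterns(m).rules == m.rules

    def test_undeclared_agent_rejected(self):
        m = parse_model(self.DECL + "'r' B(x) -> B(x) @ k\n")
        with pytest.raises(NormalizationError, match="agent 'B'"):
            normalize_patterns(m)

    def test_omitted_sites_stay_omitted(self):
        m = parse_model(self.DECL + "'r' A(site2~y) -> A(site2~x) @ k\n")
        n = normalize_patterns(m)
        assert [sp.site_name for sp in n.rules[0].lhs.agents[0].sites] == \
            ["site2"]

    def test_constraint_multiset_preserved(self):
        m = parse_model(self.DECL + "'r' A(site2~y!1,site1~u),A(site2~x!1) ->"
                        " A(site2~y,site1~u),A(site2~x) @ k\n")
        n = normalize_patterns(m)
        def constraints(model):
            out = []
            for ap in model.rules[0].lhs.agents:
                out.append(frozenset((sp.site_name, sp.state, sp.binding)
                                     for sp in ap.sites))
            return out
        assert constraints(m) == constraints(n)

    def test_normalized_materialization_validates(self):
        bad = parse_model("'r' A(s~q) -> A(s~q) @ k\n")  # A undeclared
        with pytest.raises(NormalizationError):
            materialize_model(bad, base=BASE, normalize=True)
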