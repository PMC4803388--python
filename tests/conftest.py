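"""Shared fixtures and independent brute-force oracles."""

from __future__ import annotations

import itertools
from collections import defaultdict
from typing import Dict, FrozenSet, List, Set, Tuple

import pytest
from rdflib import Graph

from rbmannot import fixtures, kappa, materialize
from rbmannot.kappa import AgentDecl, BindingKind, Model


@pytest.fixture(scope="session")
def tcs_text() -> str:
    return fixtures.tcs_model()


@pytest.fixture(scope="session")
def tcs_model_parsed(tcs_text) -> Model:
    return kappa.parse_model(tcs_text)


@pytest.fixture(scope="session")
def tcs_graph(tcs_model_parsed) -> Graph:
    return materialize.materialize_model(tcs_model_parsed)


@pytest.fixture(scope="session")
def mock_ontology_graph() -> Graph:
    g = Graph()
    g.parse(data=fixtures.mock_ontology(), format="turtle")
    return g


# --------------------------------------------------------------------------
# oracles (independent of the code paths they check)

def enumerate_state_space(agent: AgentDecl) -> int:
    """Exhaustive enumeration of internal-state assignments."""
    choices = [list(s.states) or [None] for s in agent.sites]
    return sum(1 for _ in itertools.product(*choices))


def brute_force_contact_edges(model: Model, base: str
                              ) -> Set[Tuple[Tuple, Tuple, FrozenSet[str]]]:
    """Contact edges computed directly from the parsed rules, bypassing RDF.

    Returns {(endpoint_a, endpoint_b, witness-rules)} with endpoints as
    (agent URI, site URI) in sorted order, matching ContactEdge fields.
    """
    pair_rules: Dict[Tuple, Set[str]] = defaultdict(set)
    for rule in model.rules:
        if rule.label is None:
            continue
        for side in (rule.lhs, rule.rhs):
            bonds: Dict[int, List[Tuple[str, str]]] = defaultdict(list)
            for ap in side.agents:
                for sp in ap.sites:
                    if sp.binding.kind is BindingKind.BOUND_TO:
                        bonds[sp.binding.label].append(
                            (ap.agent_name, sp.site_name))
            for label, ends in bonds.items():
                assert len(ends) == 2
                uris = sorted((f"{base}{a}", f"{base}{a}:{s}")
                              for a, s in ends)
                pair_rules[tuple(uris)].add(f"{base}{rule.label}")
    return {(a, b, frozenset(rs)) for (a, b), rs in pair_rules.items()}


def brute_force_duplicates(identities: Dict[str, Set[str]]
                           ) -> Set[Tuple[str, str, FrozenSet[str]]]:
    """Pairwise set intersection over rules' bqbiol:is object sets."""
    out = set()
    for ra, rb in itertools.combinations(sorted(identities), 2):
        shared = identities[ra] & identities[rb]
        if shared:
            out.add((ra, rb, frozenset(shared)))
    return out
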