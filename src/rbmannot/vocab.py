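"""The rbmo vocabulary and the conventional prefix table.

rbmo (namespace ``http://purl.org/rbm/rbmo#``) supplies the classes and
predicates needed to describe rule-based models in RDF: types for agents,
sites, states, rules, observables and patterns, and predicates that link a
materialized rule to the declarations it mentions.  By convention terms
beginning with an uppercase letter are classes (rdf:type targets) and terms
beginning lowercase are predicates.

Third-party namespaces used alongside rbmo (Dublin Core, BioModels biology
qualifiers, GO, SO, SBO, ChEBI, UniProt, PSI-MOD, ...) are registered here
with their conventional prefixes.  The biology-qualifier prefix is accepted
both as ``bqbiol`` (canonical) and the variant spelling ``bqiol``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict

from rdflib import Namespace

from .naming import PrefixedName

RBMO_NAMESPACE = "http://purl.org/rbm/rbmo#"

RBMO = Namespace(RBMO_NAMESPACE)
BQBIOL = Namespace("http://biomodels.net/biology-qualifiers/")
DCT = Namespace("http://purl.org/dc/terms/")
SBO = Namespace("http://identifiers.org/sbo/")
RO = Namespace("http://www.obofoundry.org/ro/ro.owl#")
SBOL = Namespace("http://sbols.org/v1#")
BIOPAX = Namespace("http://www.biopax.org/release/biopax-level3.owl#")

_PREFIXES: Dict[str, str] = {
    "rbmo": RBMO_NAMESPACE,
    "dct": str(DCT),
    "bqbiol": str(BQBIOL),
    "bqiol": str(BQBIOL),  # variant spelling, same namespace
    "go": "http://identifiers.org/go/",
    "psimod": "http://identifiers.org/psimod/",
    "so": "http://identifiers.org/so/",
    "sbo": str(SBO),
    "chebi": "http://identifiers.org/chebi/",
    "uniprot": "http://identifiers.org/uniprot/",
    "pr": "http://identifiers.org/pr/",
    "ro": str(RO),
    "owl": "http://www.w3.org/2002/07/owl#",
    "sbol": str(SBOL),
    "foaf": "http://xmlns.com/foaf/0.1/",
    "ipr": "http://identifiers.org/interpro/",
    "biopax": str(BIOPAX),
    "rdf": "http://www.w3.org/1999/02/22-rdf-syntax-ns#",
    "rdfs": "http://www.w3.org/2000/01/rdf-schema#",
}


class UnknownTermError(KeyError):
    """Requested local name is not an rbmo term."""


@dataclass(frozen=True)
class VocabTerm:
    prefixed: PrefixedName
    category: str  # "class" | "predicate"
    description: str

    @property
    def uri(self) -> str:
        return RBMO_NAMESPACE + self.prefixed.local


def _t(local: str, description: str) -> VocabTerm:
    category = "class" if local[0].isupper() else "predicate"
    return VocabTerm(PrefixedName("rbmo", local), category, description)


_TERMS: Dict[str, VocabTerm] = {
    t.prefixed.local: t for t in [
        # declarations
        _t("Model", "Type for rule-based models"),
        _t("Kappa", "Model type for models written in Kappa"),
        _t("BioNetGen", "Model type for models written in BioNetGen"),
        _t("Agent", "Type for declarations of biological entities"),
        _t("Site", "Type for sites of Agents"),
        _t("State", "Type for internal states of Sites"),
        _t("hasSite", "Predicates for linking Agents, Sites and States"),
        _t("hasState", "Predicates for linking Agents, Sites and States"),
        _t("siteOf", "Predicates for linking Agents, Sites and States"),
        _t("stateOf", "Predicates for linking Agents, Sites and States"),
        _t("Rule", "Type for interactions between agents"),
        _t("hasSubrule", "Specifies that a rule has a subrule"),
        _t("subruleOf", "Specifies that a rule has a subrule"),
        _t("Observable", "Type for agent patterns counted by a simulation"),
        # rules in RDF
        _t("Pattern", "Type of a pattern as it appears in a Rule or Observable"),
        _t("lhs", "Predicates for linking a Rule to its left and right hand "
                  "side Patterns"),
        _t("rhs", "Predicates for linking a Rule to its left and right hand "
                  "side Patterns"),
        _t("pattern", "Predicate for linking an Observable to the patterns "
                      "that it matches"),
        _t("agent", "Predicate for linking a Pattern and a site within it to "
                    "the corresponding Agent"),
        _t("status", "Specifies a status of a particular Site (and State) in "
                     "a Pattern"),
        _t("isStatusOf", "Predicates for linking a status in a Pattern to "
                         "corresponding Site and State declarations"),
        _t("internalState", "Predicates for linking a status in a Pattern to "
                            "corresponding Site and State declarations"),
        _t("isBoundBy", "Specifies the bond that a Site is bound to in a "
                        "particular Pattern. Bonds are identified via URIs"),
        _t("BoundState", "Terms denoting that a Site in a Pattern is bound "
                         "or unbound"),
        _t("UnboundState", "Terms denoting that a Site in a Pattern is bound "
                           "or unbound"),
    ]
}


def term(local: str) -> VocabTerm:
    """Look up an rbmo term by local name; raises UnknownTermError."""
    try:
        return _TERMS[local]
    except KeyError:
        raise UnknownTermError(local) from None


def terms() -> Dict[str, VocabTerm]:
    return dict(_TERMS)


def default_prefixes() -> Dict[str, str]:
    """The conventional prefix table (canonical ``bqbiol`` plus the ``bqiol``
    alias, both bound to the BioModels biology-qualifier namespace)."""
    return dict(_PREFIXES)


def turtle_preamble(base: str | None = None,
                    prefixes: Dict[str, str] | None = None) -> str:
    """Render a Turtle ``@prefix`` preamble; includes the empty prefix when
    ``base`` is given."""
    table = dict(prefixes) if prefixes is not None else default_prefixes()
    table.pop("bqiol", None)  # one spelling is enough in output
    lines = []
    if base is not None:
        lines.append(f"@prefix : <{base}> .")
    for p in sorted(table):
        lines.append(f"@prefix {p}: <{table[p]}> .")
    return "\n".join(lines) + "\n"
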