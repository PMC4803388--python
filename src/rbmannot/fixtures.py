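"""In-repo test corpus: the annotated two-component-system model and a
seeded random annotated-model generator.

``tcs_model`` is a **synthetic reconstruction** of a didactic
two-component-system (TCS) model of sporulation initiation: a sporulation
kinase (KinA, UniProt P16497) phosphorylates the response
regulator/transcription factor Spo0A, consuming ATP (ChEBI 15422);
phosphorylated Spo0A binds an operator upstream of a promoter.  The
original example file is not reproduced verbatim — printed identifiers are
used where known, and the remaining accessions, sequences, rule set and
rates are plausible stand-ins.

``random_model`` produces deterministic, guideline-conformant annotated
models for property testing, optionally planting a duplicate-rule pair
and/or a disjointness conflict whose terms are typed by the companion
``mock_ontology``.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from typing import List

MOCK_VOCAB = "http://example.org/mockvocab#"

_TCS_BASE = "http://example.org/models/tcs#"

_TCS = """\
#^ @prefix : <http://example.org/models/tcs#> .
#^ @prefix rbmo: <http://purl.org/rbm/rbmo#> .
#^ @prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .
#^ @prefix dct: <http://purl.org/dc/terms/> .
#^ @prefix bqbiol: <http://biomodels.net/biology-qualifiers/> .
#^ @prefix go: <http://identifiers.org/go/> .
#^ @prefix so: <http://identifiers.org/so/> .
#^ @prefix sbo: <http://identifiers.org/sbo/> .
#^ @prefix chebi: <http://identifiers.org/chebi/> .
#^ @prefix uniprot: <http://identifiers.org/uniprot/> .
#^ @prefix psimod: <http://identifiers.org/psimod/> .
#^ @prefix ipr: <http://identifiers.org/interpro/> .
#^ @prefix ro: <http://www.obofoundry.org/ro/ro.owl#> .
#^ @prefix sbol: <http://sbols.org/v1#> .
#^ @prefix biopax: <http://www.biopax.org/release/biopax-level3.owl#> .
#^
#^ :TCS rdf:type rbmo:Kappa ;
#^     dct:title "Two-component system" ;
#^     dct:description "Sporulation kinase KinA phosphorylates the response regulator Spo0A, which binds an operator to control a promoter." .
#^
# --- agents -----------------------------------------------------------
#^ :KinA rdf:type rbmo:Agent ;
#^     dct:isPartOf :TCS ;
#^     biopax:physicalEntity biopax:Protein ;
#^     bqbiol:is uniprot:P16497 ;
#^     ro:hasFunction go:GO:0000155 ;
#^     rbmo:hasSite :KinA:H .
#^ :KinA:H rdf:type rbmo:Site ;
#^     bqbiol:isVersionOf ipr:IPR003594 ;
#^     rbmo:hasState :KinA:H:u, :KinA:H:p .
#^ :KinA:H:u rdf:type rbmo:State ;
#^     bqbiol:is psimod:MOD:00000 .
#^ :KinA:H:p rdf:type rbmo:State ;
#^     bqbiol:is psimod:MOD:00696 .
%agent: KinA(H~u~p)
#^ :Spo0A rdf:type rbmo:Agent ;
#^     dct:isPartOf :TCS ;
#^     biopax:physicalEntity biopax:Protein ;
#^     bqbiol:is uniprot:P06534 ;
#^     rbmo:hasSite :Spo0A:RR, :Spo0A:DNAb .
#^ :Spo0A:RR rdf:type rbmo:Site ;
#^     rbmo:hasState :Spo0A:RR:u, :Spo0A:RR:p .
#^ :Spo0A:RR:u rdf:type rbmo:State ;
#^     bqbiol:is psimod:MOD:00000 .
#^ :Spo0A:RR:p rdf:type rbmo:State ;
#^     bqbiol:is psimod:MOD:00696 .
#^ :Spo0A:DNAb rdf:type rbmo:Site .
%agent: Spo0A(RR~u~p,DNAb)
#^ :Prom rdf:type rbmo:Agent ;
#^     dct:isPartOf :TCS ;
#^     biopax:physicalEntity biopax:DnaRegion ;
#^     bqbiol:isVersionOf so:SO:0000167 ;
#^     sbol:nucleotides "ttgacagctagctcagtcctaggtataatgctagc" ;
#^     rbmo:hasSite :Prom:pol .
%agent: Prom(pol)
#^ :Op rdf:type rbmo:Agent ;
#^     dct:isPartOf :TCS ;
#^     biopax:physicalEntity biopax:DnaRegion ;
#^     bqbiol:isVersionOf so:SO:0000057 ;
#^     sbol:nucleotides "tcgaaannnnntttcgaa" ;
#^     rbmo:hasSite :Op:tf .
#^ <http://example.org/models/tcs/annotations/op_location>
#^     rdf:type sbol:SequenceAnnotation ;
#^     sbol:bioStart 1 ;
#^     sbol:bioEnd 18 ;
#^     sbol:subComponent :Op ;
#^     dct:isPartOf :Prom .
%agent: Op(tf)
#^ :ATP rdf:type rbmo:Agent ;
#^     dct:isPartOf :TCS ;
#^     biopax:physicalEntity biopax:SmallMolecule ;
#^     bqbiol:is chebi:CHEBI:15422 .
%token: ATP
#^ :ADP rdf:type rbmo:Agent ;
#^     dct:isPartOf :TCS ;
#^     biopax:physicalEntity biopax:SmallMolecule ;
#^     bqbiol:is chebi:CHEBI:16761 .
%token: ADP
# --- variables --------------------------------------------------------
#^ :kp rdf:type sbo:SBO:0000002 ;
#^     dct:isPartOf :TCS ;
#^     bqbiol:isVersionOf sbo:SBO:0000009 .
%var: 'kp' 0.1
%var: 'kon' 0.01
%var: 'koff' 0.005
# --- rules ------------------------------------------------------------
#^ :Phos rdf:type rbmo:Rule ;
#^     dct:isPartOf :TCS ;
#^     bqbiol:isVersionOf go:GO:0016310 ;
#^     rbmo:hasSubrule :Phos:1 .
#^ :Phos:1 rdf:type rbmo:Rule ;
#^     dct:isPartOf :TCS ;
#^     bqbiol:isVersionOf go:GO:0006754 .
'Phos' KinA(H~u),Spo0A(RR~u) -> KinA(H~u),Spo0A(RR~p) | ATP -> ADP @ kp
#^ :TF_binding rdf:type rbmo:Rule ;
#^     dct:isPartOf :TCS ;
#^     bqbiol:isVersionOf go:GO:0008134 .
'TF_binding' Spo0A(RR~p,DNAb),Op(tf) -> Spo0A(RR~p,DNAb!1),Op(tf!1) @ kon
#^ :Cooperative_unbinding rdf:type rbmo:Rule ;
#^     dct:isPartOf :TCS ;
#^     dct:title "Cooperative unbinding" ;
#^     bqbiol:isVersionOf go:GO:0008134 .
'Cooperative_unbinding' Spo0A(DNAb!1,RR~p),Op(tf!1) -> Spo0A(DNAb,RR~p),Op(tf) @ koff
# --- observables ------------------------------------------------------
#^ :Spo0A_p rdf:type rbmo:Observable ;
#^     dct:isPartOf :TCS .
%obs: 'Spo0A_p' Spo0A(RR~p)
%init: 100 KinA(H~u)
%init: 100 Spo0A(RR~u,DNAb)
"""


def tcs_base() -> str:
    """Base URI bound to the empty prefix by the TCS fixture."""
    return _TCS_BASE


def tcs_model() -> str:
    """Source text of the annotated two-component-system example model."""
    return _TCS


def mock_ontology() -> str:
    """Turtle for a tiny local vocabulary used by generated annotations.

    Synthetic stand-in for web-retrieved ontologies: two disjoint classes
    (one reached through a subclass hop), two individuals typed by them,
    and a pool of neutral terms used as harmless identity targets.
    """
    lines = [
        f"@prefix mv: <{MOCK_VOCAB}> .",
        "@prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
        "@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .",
        "@prefix owl: <http://www.w3.org/2002/07/owl#> .",
        "",
        "mv:ClassA rdf:type owl:Class .",
        "mv:ClassB rdf:type owl:Class .",
        "mv:SubA rdfs:subClassOf mv:ClassA .",
        "mv:ClassA owl:disjointWith mv:ClassB .",
        "mv:ConflictTermA rdf:type mv:SubA .",
        "mv:ConflictTermB rdf:type mv:ClassB .",
    ]
    for i in range(10):
        lines.append(f"mv:Neutral{i} rdf:type mv:NeutralClass .")
    return "\n".join(lines) + "\n"


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the random annotated-model generator.

    Defaults emulate a small hand-written signalling model: a handful of
    agents with one to three sites, at most two internal states per site,
    and binding/unbinding/state-flip rules.  ``annotation_density`` is the
    fraction of agents and rules that carry annotations (1.0 by default so
    generated models are fully guideline-conformant).
    """
    seed: int
    n_agents: int = 4
    max_sites: int = 3
    max_states: int = 2
    n_rules: int = 6
    annotation_density: float = 1.0
    include_tokens: bool = True
    plant_duplicate: bool = False
    plant_conflict: bool = False

    def __post_init__(self):
        if self.n_agents < 1 or self.max_sites < 1 or self.n_rules < 1:
            raise ValueError("n_agents, max_sites and n_rules must be >= 1")
        if self.max_states < 0:
            raise ValueError("max_states must be >= 0")
        if not 0.0 <= self.annotation_density <= 1.0:
            raise ValueError("annotation_density must lie in [0, 1]")
        if self.plant_duplicate and self.n_rules < 2:
            raise ValueError("planting a duplicate needs n_rules >= 2")


def random_base(config: GeneratorConfig) -> str:
    return f"http://example.org/models/random{config.seed}#"


def random_model(config: GeneratorConfig) -> str:
    """Deterministic annotated Kappa model text for ``config``.

    Generated rules always have paired bond labels; generated annotations
    follow the guidelines (typed entities, attached to a model node,
    hasSite/hasState targets declared).  With ``plant_duplicate`` two rules
    share a ``bqbiol:is`` object; with ``plant_conflict`` the first agent
    is identified with the two conflicting mock-vocabulary terms.
    """
    rng = random.Random(config.seed)
    base = random_base(config)

    agents: List[dict] = []
    for i in range(config.n_agents):
        sites = []
        for j in range(rng.randint(1, config.max_sites)):
            n_states = rng.randint(0, config.max_states)
            sites.append((f"s{j}", [f"st{k}" for k in range(n_states)]))
        agents.append({"name": f"Ag{i}", "sites": sites})

    lines: List[str] = [
        f"#^ @prefix : <{base}> .",
        "#^ @prefix rbmo: <http://purl.org/rbm/rbmo#> .",
        "#^ @prefix rdf: <http://www.w3.org/1999/02/22-rdf-syntax-ns#> .",
        "#^ @prefix dct: <http://purl.org/dc/terms/> .",
        "#^ @prefix bqbiol: <http://biomodels.net/biology-qualifiers/> .",
        f"#^ @prefix mv: <{MOCK_VOCAB}> .",
        "#^ :M rdf:type rbmo:Kappa ;",
        f'#^     dct:title "Random annotated model (seed {config.seed})" .',
    ]

    def annotate_agent(a: dict, extra: List[str]) -> None:
        name = a["name"]
        lines.append(f"#^ :{name} rdf:type rbmo:Agent ;")
        lines.append("#^     dct:isPartOf :M ;")
        for line in extra:
            lines.append(f"#^     {line} ;")
        site_refs = ", ".join(f":{name}:{s}" for s, _ in a["sites"])
        if site_refs:
            lines.append(f"#^     rbmo:hasSite {site_refs} .")
        else:
            lines[-1] = lines[-1].rstrip(" ;") + " ."
        for s, states in a["sites"]:
            if states:
                refs = ", ".join(f":{name}:{s}:{st}" for st in states)
                lines.append(f"#^ :{name}:{s} rdf:type rbmo:Site ;")
                lines.append(f"#^     rbmo:hasState {refs} .")
            else:
                lines.append(f"#^ :{name}:{s} rdf:type rbmo:Site .")

    for i, a in enumerate(agents):
        annotated = rng.random() < config.annotation_density
        extra = [f"bqbiol:is mv:AgentTerm{config.seed}_{i}"]
        if config.plant_conflict and i == 0:
            extra = ["bqbiol:is mv:ConflictTermA",
                     "bqbiol:is mv:ConflictTermB"]
            annotated = True
        if annotated:
            annotate_agent(a, extra)
        sig = ",".join(s + "".join("~" + st for st in states)
                       for s, states in a["sites"])
        lines.append(f"%agent: {a['name']}({sig})")

    if config.include_tokens:
        lines.append("%token: tokX")
        lines.append("%token: tokY")

    stateful = [(a["name"], s, states) for a in agents
                for s, states in a["sites"] if states]

    rule_texts: List[str] = []
    for i in range(config.n_rules):
        kind = rng.choice(["bind", "unbind", "flip"] if stateful
                          else ["bind", "unbind"])
        a1 = rng.choice(agents)
        s1 = rng.choice(a1["sites"])[0]
        if kind == "flip":
            an, sn, states = rng.choice(stateful)
            st_from, st_to = rng.choice(states), rng.choice(states)
            body = (f"{an}({sn}~{st_from}) -> {an}({sn}~{st_to})")
        else:
            a2 = rng.choice(agents)
            s2 = rng.choice(a2["sites"])[0]
            free = f"{a1['name']}({s1}),{a2['name']}({s2})"
            bound = f"{a1['name']}({s1}!1),{a2['name']}({s2}!1)"
            body = f"{free} -> {bound}" if kind == "bind" \
                else f"{bound} -> {free}"
        if config.include_tokens and i == 0:
            body += " | tokX -> tokY"
        rule_texts.append(f"'r{i}' {body} @ k{i}")

    for i, text in enumerate(rule_texts):
        annotated = rng.random() < config.annotation_density
        identity = f"mv:RuleTerm{config.seed}_{i}"
        planted = config.plant_duplicate and i in (0, 1)
        if planted:
            annotated = True
        if annotated:
            lines.append(f"#^ :r{i} rdf:type rbmo:Rule ;")
            if planted:
                lines.append(f"#^     bqbiol:is mv:SharedReaction{config.seed} ;")
            lines.append(f"#^     bqbiol:is {identity} ;")
            lines.append("#^     dct:isPartOf :M .")
            if i == 0 and config.include_tokens:
                lines.append(f"#^ :r0 rbmo:hasSubrule :r0:1 .")
                lines.append(f"#^ :r0:1 rdf:type rbmo:Rule ; dct:isPartOf :M .")
        lines.append(f"%var: 'k{i}' {rng.uniform(0.001, 1.0):.6f}")
        lines.append(text)

    first = agents[0]
    lines.append(f"%obs: 'Obs0' {first['name']}()")
    return "\n".join(lines) + "\n"
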