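"""Materialize a parsed model into RDF and merge it with its annotations.

Materialization re-expresses the rules themselves as triples so that model
structure and author metadata form one uniform, queryable graph: the model
node is typed ``rbmo:Kappa``; each agent declaration becomes an
``rbmo:Agent`` with ``hasSite``/``hasState`` chains; each labeled rule
becomes an ``rbmo:Rule`` with ``rbmo:lhs``/``rbmo:rhs`` pattern nodes; each
site mention in a pattern becomes a *status node* recording its internal
state (``rbmo:internalState``), its binding (``rbmo:status`` of
``rbmo:BoundState``/``rbmo:UnboundState``, plus ``rbmo:isBoundBy`` a bond
URI for explicit bonds) and the site declaration it refers to
(``rbmo:isStatusOf``).

Node identity is deterministic rather than blank: status and pattern nodes
are skolemized with the entity-naming joiner (``rule:lhs``,
``rule:lhs:<agentPosition>:<site>``; bonds as ``rule:<side>:bond:<label>``),
which makes output diffable and queryable across runs.  Multiple
occurrences of one agent in a pattern are distinguished by their 1-based
textual position.
"""

from __future__ import annotations

import warnings
from dataclasses import replace
from typing import List, Optional, Sequence, Union

from rdflib import Graph, Literal, RDF, URIRef

from . import vocab
from .annotations import (MissingEmptyPrefixError, declared_empty_prefix,
                          parse_annotations)
from .kappa import (AgentPattern, BindingKind, Model, Pattern, Rule,
                    SitePattern)
from .naming import PrefixedName, entity_name
from .vocab import DCT, RBMO, SBO


class NormalizationError(ValueError):
    """A pattern names an agent, site or state with no declaration."""


def _uri(base: str, path: Sequence[str]) -> URIRef:
    return URIRef(base + entity_name(path).local)


def bond_uri(rule: Union[PrefixedName, str], side: str, label: int,
             base: str = "") -> str:
    """Deterministic URI for bond ``label`` on ``side`` of ``rule``.

    Injective over (rule, side, label): the three components are joined by
    the entity-naming algorithm under a reserved ``bond`` segment.
    """
    if label < 1:
        raise ValueError("bond labels are positive integers")
    if side not in ("lhs", "rhs", "pattern"):
        raise ValueError(f"unknown rule side {side!r}")
    if isinstance(rule, PrefixedName):
        local = rule.local
    else:
        local = rule[1:] if rule.startswith(":") else rule
    return base + ":".join([local, side, "bond", str(label)])


# --------------------------------------------------------------------------
# normalization

def normalize_patterns(model: Model) -> Model:
    """Resolve every pattern against the declarations and put sites into
    declaration order.  Idempotent; omitted sites stay omitted (absence
    means unconstrained).  Raises :class:`NormalizationError` for undeclared
    agents, sites or states."""

    def norm_pattern(p: Pattern) -> Pattern:
        agents: List[AgentPattern] = []
        for ap in p.agents:
            decl = model.agent(ap.agent_name)
            if decl is None:
                raise NormalizationError(
                    f"agent {ap.agent_name!r} is not declared")
            order = {s.name: i for i, s in enumerate(decl.sites)}
            for sp in ap.sites:
                if sp.site_name not in order:
                    raise NormalizationError(
                        f"site {sp.site_name!r} is not declared on agent "
                        f"{ap.agent_name!r}")
                if sp.state is not None:
                    sd = decl.site(sp.site_name)
                    if sp.state not in sd.state_names():
                        raise NormalizationError(
                            f"state {sp.state!r} is not declared for site "
                            f"{ap.agent_name}.{sp.site_name}")
            agents.append(replace(
                ap, sites=tuple(sorted(ap.sites,
                                       key=lambda s: order[s.site_name]))))
        return Pattern(tuple(agents))

    def norm_rule(r: Rule) -> Rule:
        return replace(r, lhs=norm_pattern(r.lhs), rhs=norm_pattern(r.rhs),
                       subrules=tuple(norm_rule(s) for s in r.subrules))

    return Model(
        agents=list(model.agents),
        rules=[norm_rule(r) for r in model.rules],
        observables=[replace(o, pattern=norm_pattern(o.pattern))
                     for o in model.observables],
        variables=list(model.variables),
        annotation_lines=list(model.annotation_lines),
        inits=list(model.inits),
        source_lines=list(model.source_lines),
    )


# --------------------------------------------------------------------------
# materialization

def _materialize_pattern(g: Graph, base: str, prefix_path: List[str],
                         pattern: Pattern, owner: URIRef,
                         link_pred) -> None:
    p = _uri(base, prefix_path)
    g.add((owner, link_pred, p))
    g.add((p, RDF.type, RBMO.Pattern))
    for ap in pattern.agents:
        agent_decl = _uri(base, [ap.agent_name])
        g.add((p, RBMO.agent, agent_decl))
        for sp in ap.sites:
            s = _uri(base, prefix_path + [str(ap.position), sp.site_name])
            g.add((s, DCT.isPartOf, p))
            g.add((s, RBMO.agent, agent_decl))
            g.add((s, RBMO.isStatusOf,
                   _uri(base, [ap.agent_name, sp.site_name])))
            if sp.state is not None:
                g.add((s, RBMO.internalState,
                       _uri(base, [ap.agent_name, sp.site_name, sp.state])))
            kind = sp.binding.kind
            if kind is BindingKind.UNBOUND:
                g.add((s, RBMO.status, RBMO.UnboundState))
            elif kind is BindingKind.BOUND_UNKNOWN:
                g.add((s, RBMO.status, RBMO.BoundState))
            elif kind is BindingKind.BOUND_TO:
                g.add((s, RBMO.status, RBMO.BoundState))
                g.add((s, RBMO.isBoundBy,
                       URIRef(bond_uri(entity_name(prefix_path[:-1]),
                                       prefix_path[-1], sp.binding.label,
                                       base))))
            # '?' (unspecified) deliberately emits no status triples


def _materialize_rule(g: Graph, base: str, path: List[str], rule: Rule,
                      model_node: URIRef) -> None:
    r = _uri(base, path)
    g.add((r, RDF.type, RBMO.Rule))
    g.add((r, DCT.isPartOf, model_node))
    _materialize_pattern(g, base, path + ["lhs"], rule.lhs, r, RBMO.lhs)
    _materialize_pattern(g, base, path + ["rhs"], rule.rhs, r, RBMO.rhs)
    for i, sub in enumerate(rule.subrules, 1):
        sub_path = path + [str(i)]
        sr = _uri(base, sub_path)
        g.add((r, RBMO.hasSubrule, sr))
        g.add((sr, RBMO.subruleOf, r))
        _materialize_rule(g, base, sub_path, sub, model_node)


def materialize_model(model: Model, base: Optional[str] = None,
                      normalize: bool = False) -> Graph:
    """Author annotations merged with generated model-structure triples.

    ``base`` supplies the empty-prefix namespace when the annotation
    document does not declare one.  With ``normalize`` set, patterns are
    first resolved against declarations (site order, name/state validity).
    Unlabeled rules cannot be named and are skipped with a warning.
    """
    declared = declared_empty_prefix(model.annotation_lines)
    effective_base = declared or base
    if effective_base is None:
        raise MissingEmptyPrefixError(
            "no base URI: annotations declare no empty prefix and none was "
            "supplied")
    if normalize:
        model = normalize_patterns(model)

    g = parse_annotations(model.annotation_lines, base=effective_base)
    g.bind("", effective_base)
    for prefix, ns in vocab.default_prefixes().items():
        if prefix != "bqiol":
            g.bind(prefix, ns, override=False)

    model_nodes = sorted(
        s for t in (RBMO.Kappa, RBMO.BioNetGen, RBMO.Model)
        for s in g.subjects(RDF.type, t))
    model_node = model_nodes[0] if model_nodes else URIRef(effective_base)
    if not model_nodes:
        g.add((model_node, RDF.type, RBMO.Kappa))

    for a in model.agents:
        au = _uri(effective_base, [a.name])
        g.add((au, RDF.type, RBMO.Agent))
        g.add((au, DCT.isPartOf, model_node))
        for s in a.sites:
            su = _uri(effective_base, [a.name, s.name])
            g.add((au, RBMO.hasSite, su))
            g.add((su, RBMO.siteOf, au))
            g.add((su, RDF.type, RBMO.Site))
            for st in s.states:
                stu = _uri(effective_base, [a.name, s.name, st.name])
                g.add((su, RBMO.hasState, stu))
                g.add((stu, RBMO.stateOf, su))
                g.add((stu, RDF.type, RBMO.State))

    for rule in model.rules:
        if rule.label is None:
            warnings.warn("skipping unlabeled rule during materialization",
                          UserWarning, stacklevel=2)
            continue
        _materialize_rule(g, effective_base, [rule.label], rule, model_node)

    for o in model.observables:
        ou = _uri(effective_base, [o.label])
        g.add((ou, RDF.type, RBMO.Observable))
        g.add((ou, DCT.isPartOf, model_node))
        _materialize_pattern(g, effective_base, [o.label, "pattern"],
                             o.pattern, ou, RBMO.pattern)

    for v in model.variables:
        vu = _uri(effective_base, [v.label])
        g.add((vu, RDF.type, URIRef(SBO + "SBO:0000002")))
        g.add((vu, DCT.isPartOf, model_node))

    return g
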