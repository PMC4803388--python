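"""Analyses over the materialized model graph.

Three applications of the uniform RDF representation:

* **contact maps** — the undirected graph of (agent, site) pairs that are
  bound together somewhere in the rules.  Both rule sides witness a
  contact (an unbinding rule still proves the two sites can touch).  The
  DOT renderer enriches nodes and edges with biological information pulled
  from the annotations (identifiers, molecular functions, sequences).

* **duplicate-rule detection** — rules claiming the same biological
  identity (a shared ``bqbiol:is`` object) are candidate duplicates when
  composing models; a join on that predicate with self-pairs filtered out.

* **consistency checking** — ``bqbiol:is`` claims are strengthened to
  ``owl:sameAs``; pooling the rdf:types across each sameAs equivalence
  class and walking ``rdfs:subClassOf`` ancestry exposes entities asserted
  to belong to two ``owl:disjointWith`` classes.  This is a sound but
  deliberately incomplete approximation of full OWL reasoning; the merged
  graph can be exported for an external reasoner when completeness
  matters.  Every reported conflict carries a replayable proof chain of
  triples from the input graphs.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Optional, Sequence, Set, Tuple

from rdflib import Graph, Literal, OWL, RDF, RDFS, URIRef

from .vocab import BQBIOL, DCT, RBMO, RO, SBOL

Triple = Tuple

_BQBIOL_IS = BQBIOL["is"]


def _local(uri: str) -> str:
    """Human-readable tail of a URI (after '#' or the last '/')."""
    s = str(uri)
    if "#" in s:
        return s.rsplit("#", 1)[1]
    return s.rstrip("/").rsplit("/", 1)[-1]


# --------------------------------------------------------------------------
# contact maps

@dataclass(frozen=True)
class ContactEdge:
    """An undirected site-site contact, with the rules that witness it."""
    endpoint_a: Tuple[str, str]  # (agent URI, site URI), canonical order
    endpoint_b: Tuple[str, str]
    rules: FrozenSet[str]

    def __post_init__(self):
        if not self.rules:
            raise ValueError("a contact edge needs at least one witness rule")


def contact_map(graph: Graph) -> Set[ContactEdge]:
    """Derive the contact map from a materialized graph.

    One edge per unordered (agent, site)-(agent, site) pair sharing a bond
    URI on either side of any rule; dimerization self-edges are allowed.
    Only bonds belonging to ``rbmo:Rule``-typed owners count (observable
    patterns describe measurements, not interactions).
    """
    if not any(True for _ in graph.subjects(RDF.type, RBMO.Kappa)) and \
       not any(True for _ in graph.subjects(RDF.type, RBMO.BioNetGen)) and \
       not any(True for _ in graph.subjects(RDF.type, RBMO.Model)):
        raise ValueError("graph does not look like a materialized model "
                         "(no model-typed node)")
    rules = set(graph.subjects(RDF.type, RBMO.Rule))
    bond_endpoints: Dict[URIRef, List[URIRef]] = defaultdict(list)
    for status, bond in graph.subject_objects(RBMO.isBoundBy):
        bond_endpoints[bond].append(status)

    edges: Dict[Tuple, Set[str]] = defaultdict(set)
    for bond, statuses in bond_endpoints.items():
        if len(statuses) != 2:
            continue
        endpoints = []
        owner = None
        for st in statuses:
            agent = graph.value(st, RBMO.agent)
            site = graph.value(st, RBMO.isStatusOf)
            endpoints.append((str(agent), str(site)))
            pattern = graph.value(st, DCT.isPartOf)
            for pred in (RBMO.lhs, RBMO.rhs, RBMO.pattern):
                o = graph.value(predicate=pred, object=pattern)
                if o is not None:
                    owner = o
        if owner is None or owner not in rules:
            continue
        a, b = sorted(endpoints)
        edges[(a, b)].add(str(owner))

    return {ContactEdge(a, b, frozenset(rs))
            for (a, b), rs in edges.items()}


def _annotation_labels(graph: Graph, uri: URIRef,
                       reverse_prefixes: Dict[str, str]) -> List[str]:
    """Short descriptive strings for a node, pulled from its annotations."""
    out: List[str] = []
    for title in graph.objects(uri, DCT.title):
        out.append(str(title))
    for pred in (_BQBIOL_IS, RO.hasFunction):
        for o in graph.objects(uri, pred):
            out.append(_curie(str(o), reverse_prefixes))
    for o in graph.objects(uri, SBOL.nucleotides):
        seq = str(o)
        out.append(seq if len(seq) <= 18 else seq[:15] + "...")
    return out


def _curie(uri: str, reverse_prefixes: Dict[str, str]) -> str:
    for ns, prefix in reverse_prefixes.items():
        if uri.startswith(ns):
            return f"{prefix}:{uri[len(ns):]}"
    return _local(uri)


def _dot_escape(s: str) -> str:
    return s.replace("\\", "\\\\").replace('"', '\\"').replace("|", "\\|") \
            .replace("{", "\\{").replace("}", "\\}").replace("<", "\\<") \
            .replace(">", "\\>")


def render_contact_dot(edges: Set[ContactEdge],
                       graph: Optional[Graph] = None) -> str:
    """GraphViz DOT for an annotated contact map.

    One record node per agent (sites as sub-records); annotation values
    (titles, identifier CURIEs, functions, sequences) decorate agents,
    sites and edges when a materialized graph is supplied.
    """
    from . import vocab
    reverse = {ns: p for p, ns in vocab.default_prefixes().items()
               if p != "bqiol"}

    agent_sites: Dict[str, Set[str]] = defaultdict(set)
    agent_names: Dict[str, str] = {}
    for e in edges:
        for agent, site in (e.endpoint_a, e.endpoint_b):
            agent_sites[agent].add(site)
            agent_names.setdefault(agent, _local(agent).split(":")[0])
    if graph is not None:
        for a in graph.subjects(RDF.type, RBMO.Agent):
            agent_sites.setdefault(str(a), set())
            agent_names.setdefault(str(a), _local(str(a)).split(":")[0])
            for s in graph.objects(a, RBMO.hasSite):
                agent_sites[str(a)].add(str(s))

    lines = ["graph contact_map {", "  node [shape=record];"]
    port_of: Dict[Tuple[str, str], str] = {}
    for agent in sorted(agent_sites):
        name = agent_names[agent]
        head = name
        if graph is not None:
            notes = _annotation_labels(graph, URIRef(agent), reverse)
            if notes:
                head += "\\n" + "\\n".join(_dot_escape(n) for n in notes)
        cells = [head]
        for i, site in enumerate(sorted(agent_sites[agent])):
            port = f"s{i}"
            port_of[(agent, site)] = port
            label = _local(site).split(":")[-1]
            if graph is not None:
                notes = _annotation_labels(graph, URIRef(site), reverse)
                if notes:
                    label += "\\n" + "\\n".join(_dot_escape(n) for n in notes)
            cells.append(f"<{port}> {label}")
        lines.append(f'  "{name}" [label="{"|".join(cells)}"];')

    for e in sorted(edges, key=lambda e: (e.endpoint_a, e.endpoint_b)):
        (a_agent, a_site), (b_agent, b_site) = e.endpoint_a, e.endpoint_b
        attrs = ""
        if graph is not None:
            notes: List[str] = []
            for r in sorted(e.rules):
                notes.append(_local(r))
                notes.extend(_annotation_labels(graph, URIRef(r), reverse))
            if notes:
                attrs = f' [label="{_dot_escape("; ".join(notes))}"]'
        pa = port_of.get((a_agent, a_site), "")
        pb = port_of.get((b_agent, b_site), "")
        na, nb = agent_names[a_agent], agent_names[b_agent]
        lines.append(f'  "{na}":{pa} -- "{nb}":{pb}{attrs};')
    lines.append("}")
    return "\n".join(lines) + "\n"


# --------------------------------------------------------------------------
# duplicate rules

@dataclass(frozen=True)
class DuplicatePair:
    """Two distinct rules sharing at least one ``bqbiol:is`` identity."""
    rule_a: str
    rule_b: str
    shared: FrozenSet[str]

    def __post_init__(self):
        if self.rule_a >= self.rule_b:
            raise ValueError("rule_a must sort before rule_b")
        if not self.shared:
            raise ValueError("shared identity set must be non-empty")


def find_duplicate_rules(graph: Graph) -> Set[DuplicatePair]:
    """Join ``rbmo:Rule``-typed subjects on ``bqbiol:is``, excluding
    self-comparison and deduplicating the symmetric pair."""
    identities: Dict[str, Set[str]] = {}
    for r in graph.subjects(RDF.type, RBMO.Rule):
        objs = {str(o) for o in graph.objects(r, _BQBIOL_IS)}
        if objs:
            identities[str(r)] = objs
    rules = sorted(identities)
    out: Set[DuplicatePair] = set()
    for i, ra in enumerate(rules):
        for rb in rules[i + 1:]:
            shared = identities[ra] & identities[rb]
            if shared:
                out.add(DuplicatePair(ra, rb, frozenset(shared)))
    return out


# --------------------------------------------------------------------------
# consistency

def expand_sameas(graph: Graph) -> Graph:
    """A new graph = input plus ``(s, owl:sameAs, o)`` for every
    ``(s, bqbiol:is, o)``.  The input graph is left unmodified."""
    g = Graph()
    for prefix, ns in graph.namespaces():
        g.bind(prefix, ns)
    for t in graph:
        g.add(t)
    for s, o in graph.subject_objects(_BQBIOL_IS):
        g.add((s, OWL.sameAs, o))
    return g


@dataclass(frozen=True)
class Conflict:
    """An entity asserted to inhabit two disjoint classes.

    ``chain`` is the proof: sameAs steps connecting the typed members,
    the two type assertions, subclass ancestry steps, and the
    ``owl:disjointWith`` statement — every triple replayable from the
    merged input."""
    entity: str
    class_a: str
    class_b: str
    chain: Tuple[Triple, ...]


def _component_paths(adj: Dict, triples: Dict) -> Iterable[Tuple[Set, Dict]]:
    """Connected components of the sameAs graph with spanning-tree paths.

    Yields (members, path) where path[m] is the list of sameAs triples
    linking the component root to m."""
    seen: Set = set()
    for start in sorted(adj, key=str):
        if start in seen:
            continue
        members = {start}
        path: Dict = {start: []}
        queue = [start]
        seen.add(start)
        while queue:
            cur = queue.pop(0)
            for nxt in sorted(adj[cur], key=str):
                if nxt in seen:
                    continue
                seen.add(nxt)
                members.add(nxt)
                path[nxt] = path[cur] + [triples[(cur, nxt)]]
                queue.append(nxt)
        yield members, path


def find_conflicts(graph: Graph,
                   ontologies: Sequence[Graph] = ()) -> List[Conflict]:
    """Detect disjointness conflicts in the merged graph.

    Computes owl:sameAs equivalence classes (symmetric-transitive closure),
    pools rdf:type assertions within each class, lifts them through the
    rdfs:subClassOf transitive closure, and reports a conflict whenever two
    pooled types (or their ancestors) are owl:disjointWith.  One conflict
    is reported per (equivalence class, unordered type pair).
    """
    merged = Graph()
    for src in (graph, *ontologies):
        for t in src:
            merged.add(t)

    # sameAs adjacency (undirected), remembering a witnessing triple per edge
    adj: Dict = defaultdict(set)
    edge_triple: Dict = {}
    for s, o in merged.subject_objects(OWL.sameAs):
        if isinstance(o, Literal):
            continue
        adj[s].add(o)
        adj[o].add(s)
        edge_triple.setdefault((s, o), (s, OWL.sameAs, o))
        edge_triple.setdefault((o, s), (s, OWL.sameAs, o))
    for node in set(merged.subjects(RDF.type)):
        adj[node]  # ensure singleton components exist

    # subclass ancestry with paths
    super_of: Dict = defaultdict(set)
    for sub, sup in merged.subject_objects(RDFS.subClassOf):
        super_of[sub].add(sup)

    def ancestors(cls) -> Dict:
        """cls and its superclasses, each mapped to the subClassOf triples
        proving the ascent."""
        out: Dict = {cls: []}
        queue = [cls]
        while queue:
            cur = queue.pop(0)
            for sup in sorted(super_of[cur], key=str):
                if sup in out:
                    continue
                out[sup] = out[cur] + [(cur, RDFS.subClassOf, sup)]
                queue.append(sup)
        return out

    disjoint: Dict[FrozenSet, Triple] = {}
    for a, b in merged.subject_objects(OWL.disjointWith):
        disjoint.setdefault(frozenset((a, b)), (a, OWL.disjointWith, b))

    conflicts: List[Conflict] = []
    seen_keys: Set = set()
    for members, path in _component_paths(adj, edge_triple):
        typed = []
        for m in sorted(members, key=str):
            for t in sorted(merged.objects(m, RDF.type), key=str):
                typed.append((m, t))
        for i, (m1, t1) in enumerate(typed):
            anc1 = ancestors(t1)
            for m2, t2 in typed[i:]:
                if m1 == m2 and t1 == t2:
                    continue
                key = (min(str(m) for m in members), frozenset((t1, t2)))
                if key in seen_keys:
                    continue
                anc2 = ancestors(t2)
                hit = None
                for a1, p1 in anc1.items():
                    for a2, p2 in anc2.items():
                        dj = disjoint.get(frozenset((a1, a2)))
                        if dj is not None and a1 != a2:
                            hit = (a1, p1, a2, p2, dj)
                            break
                    if hit:
                        break
                if hit is None:
                    continue
                a1, p1, a2, p2, dj = hit
                chain: List[Triple] = []
                # sameAs path between the two typed members
                pm1, pm2 = path[m1], path[m2]
                common = 0
                for x, y in zip(pm1, pm2):
                    if x == y:
                        common += 1
                    else:
                        break
                chain.extend(reversed(pm1[common:]))
                chain.extend(pm2[common:])
                chain.append((m1, RDF.type, t1))
                chain.append((m2, RDF.type, t2))
                chain.extend(p1)
                chain.extend(p2)
                chain.append(dj)
                seen_keys.add(key)
                conflicts.append(Conflict(
                    entity=str(min((str(m) for m in members))),
                    class_a=str(t1), class_b=str(t2),
                    chain=tuple(chain)))
    conflicts.sort(key=lambda c: (c.entity, c.class_a, c.class_b))
    return conflicts


def check_consistency(graph: Graph,
                      ontologies: Sequence[Graph] = ()) -> List[Conflict]:
    """The full workflow: strengthen bqbiol:is to owl:sameAs, merge the
    supplied ontology graphs, and search for disjointness conflicts."""
    return find_conflicts(expand_sameas(graph), ontologies)


def merged_graph(graph: Graph, ontologies: Sequence[Graph] = ()) -> Graph:
    """The sameAs-expanded model graph merged with the ontologies — the
    input one would hand to an external OWL reasoner."""
    g = expand_sameas(graph)
    for ont in ontologies:
        for t in ont:
            g.add(t)
    return g


def render_conflicts(conflicts: Sequence[Conflict]) -> str:
    """Human-readable conflict report with numbered proof steps."""
    if not conflicts:
        return "no conflicts found\n"
    out = []
    for i, c in enumerate(conflicts, 1):
        out.append(f"conflict {i}: <{c.entity}> is asserted to be both "
                   f"<{c.class_a}> and <{c.class_b}>")
        for j, (s, p, o) in enumerate(c.chain, 1):
            out.append(f"  {j}. {s} {p} {o}")
    return "\n".join(out) + "\n"
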