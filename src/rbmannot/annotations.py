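"""Author-supplied annotations embedded in ``#^`` comment lines.

A model file's annotation lines, once the two-character ``#^`` delimiter is
stripped and the lines concatenated, form a single RDF/Turtle document.
Extraction therefore has exactly the semantics of the shell pipeline
``grep '^#\\^' | sed 's/^#\\^//'``: only lines whose first two characters
are ``#^`` count (an indented ``#^`` or ``# ^`` is an ordinary comment) and
nothing but the delimiter is removed.

Model entities are referenced from the Turtle document via empty-prefix
names produced by :mod:`rbmannot.naming`, so the document must bind the
empty prefix to the model's base URI (or one must be supplied at parse
time).

``check_guidelines`` audits a model+annotation pair against the annotation
guidelines: every empty-prefix subject must name a real model entity,
agents and rules should be typed and attached to a model node, and
hasSite/hasState links must point at declared sites/states.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from rdflib import Graph, RDF, URIRef

from . import vocab
from .kappa import Model
from .naming import entity_name, resolve
from .vocab import RBMO, DCT

_LOCAL_NAME_RE = re.compile(r"^[A-Za-z0-9_][A-Za-z0-9_.\-]*$")
_EMPTY_PREFIX_RE = re.compile(
    r"^\s*(?:@prefix\s+:\s*<|[Pp][Rr][Ee][Ff][Ii][Xx]\s+:\s*<)")
_MODEL_TYPES = (RBMO.Model, RBMO.Kappa, RBMO.BioNetGen)


class AnnotationError(ValueError):
    pass


class AnnotationSyntaxError(AnnotationError):
    """Turtle syntax error, reported against the model-file line number."""

    def __init__(self, message: str, file_line: Optional[int] = None):
        self.file_line = file_line
        loc = f" (model file line {file_line})" if file_line else ""
        super().__init__(message + loc)


class MissingEmptyPrefixError(AnnotationError):
    """The document uses the empty prefix but neither declares it nor was a
    base URI supplied."""


def extract_annotation_lines(text: str) -> List[str]:
    """All lines beginning exactly with ``#^``, delimiter removed, in order."""
    return [line[2:] for line in text.split("\n") if line.startswith("#^")]


def extract_annotation_lines_numbered(text: str) -> List[Tuple[int, str]]:
    """Like :func:`extract_annotation_lines` but with 1-based source lines."""
    return [(i, line[2:]) for i, line in enumerate(text.split("\n"), 1)
            if line.startswith("#^")]


def declared_empty_prefix(lines: List[str]) -> Optional[str]:
    """The base URI bound to the empty prefix by the document, if any."""
    for line in lines:
        if _EMPTY_PREFIX_RE.match(line):
            m = re.search(r"<([^>]*)>", line)
            if m:
                return m.group(1)
    return None


def parse_annotations(lines: List[str], base: Optional[str] = None,
                      line_numbers: Optional[List[int]] = None) -> Graph:
    """Parse extracted annotation lines into an rdflib Graph.

    If the document does not itself bind the empty prefix and ``base`` is
    given, ``@prefix : <base> .`` is injected before parsing.  Syntax errors
    are mapped back to model-file line numbers when ``line_numbers`` (one
    per input line) is provided.
    """
    doc = "\n".join(lines)
    offset = 0
    if not doc.strip():
        return Graph()
    if declared_empty_prefix(lines) is None and base is not None:
        doc = f"@prefix : <{base}> .\n" + doc
        offset = 1
    g = Graph()
    try:
        g.parse(data=doc, format="turtle")
    except Exception as e:  # rdflib BadSyntax
        msg = str(e)
        if re.search(r'Prefix\s+":"\s+not bound', msg):
            raise MissingEmptyPrefixError(
                "annotations use the empty prefix but do not declare it and "
                "no base URI was supplied") from None
        file_line = None
        m = re.search(r"line\s+(\d+)", msg)
        if m:
            doc_line = int(m.group(1)) - offset
            if line_numbers and 1 <= doc_line <= len(line_numbers):
                file_line = line_numbers[doc_line - 1]
        raise AnnotationSyntaxError(
            f"invalid Turtle in annotations: {msg.splitlines()[0]}",
            file_line) from None
    return g


def annotation_graph(text: str, base: Optional[str] = None) -> Graph:
    """Extract and parse the annotation document of a whole model file."""
    numbered = extract_annotation_lines_numbered(text)
    return parse_annotations([c for _, c in numbered], base=base,
                             line_numbers=[n for n, _ in numbered])


def embed_annotations(triples: Graph, base: Optional[str] = None) -> List[str]:
    """Serialize a graph as Turtle and prefix every line with ``#^``.

    extract -> parse of the result recovers an isomorphic graph.
    """
    g = Graph()
    if base is not None:
        g.bind("", base)
    for prefix, ns in vocab.default_prefixes().items():
        if prefix != "bqiol":
            g.bind(prefix, ns, override=False)
    for t in triples:
        g.add(t)
    text = g.serialize(format="turtle")
    lines = text.splitlines()
    while lines and not lines[-1].strip():
        lines.pop()
    if not any(line.lstrip().startswith(("@prefix", "PREFIX")) for line in lines):
        pre = vocab.turtle_preamble(base).splitlines()
        lines = pre + lines
    return ["#^" + line for line in lines]


# --------------------------------------------------------------------------
# guideline checking

@dataclass(frozen=True)
class Finding:
    severity: str  # "error" | "warning"
    entity: Optional[str]
    message: str


@dataclass
class GuidelineReport:
    findings: List[Finding] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.findings

    def errors(self) -> List[Finding]:
        return [f for f in self.findings if f.severity == "error"]

    def to_tsv(self) -> str:
        rows = ["severity\tentity\tmessage"]
        rows += [f"{f.severity}\t{f.entity or ''}\t{f.message}"
                 for f in self.findings]
        return "\n".join(rows) + "\n"

    def __iter__(self):
        return iter(self.findings)

    def __len__(self):
        return len(self.findings)


def entity_paths(model: Model) -> List[List[str]]:
    """Declaration paths of every nameable entity in the model."""
    paths: List[List[str]] = []
    for a in model.agents:
        paths.append([a.name])
        for s in a.sites:
            paths.append([a.name, s.name])
            for st in s.states:
                paths.append([a.name, s.name, st.name])
    for r in model.rules:
        if r.label is None:
            continue
        paths.append([r.label])
        for i in range(1, len(r.subrules) + 1):
            paths.append([r.label, str(i)])
    for o in model.observables:
        paths.append([o.label])
    for v in model.variables:
        paths.append([v.label])
    return paths


def entity_uris(model: Model, base: str) -> Dict[str, str]:
    """Map rendered empty-prefix names to absolute URIs for all entities."""
    table = {"": base}
    return {entity_name(p).render(): resolve(entity_name(p), table)
            for p in entity_paths(model)}


def check_guidelines(model: Model, triples: Graph,
                     base: Optional[str] = None) -> GuidelineReport:
    """Audit annotations against the annotation guidelines.

    Reported findings: (a) empty-prefix subjects that name no model entity
    (error); (b) agents/rules without ``rdf:type`` rbmo:Agent/rbmo:Rule
    (warning); (c) typed agents/rules not ``dct:isPartOf`` a model-typed
    node (warning); (d) hasSite/hasState targets that are not declared
    sites/states of that subject (error); (e) rule labels that are not valid
    Turtle local names (error).
    """
    if base is None:
        base = declared_empty_prefix(model.annotation_lines)
    if base is None:
        raise MissingEmptyPrefixError(
            "cannot resolve entity names: no base URI known")
    findings: List[Finding] = []
    uris = entity_uris(model, base)
    known = set(uris.values())
    model_nodes = {s for t in _MODEL_TYPES for s in triples.subjects(RDF.type, t)}

    # (e) label syntax — checked first, in declaration order
    for r in model.rules:
        if r.label is not None and not _LOCAL_NAME_RE.match(r.label):
            findings.append(Finding(
                "error", None,
                f"rule label {r.label!r} is not a valid Turtle/SPARQL local "
                f"name"))

    # (a) orphan subjects
    subjects = sorted({s for s in triples.subjects()
                       if isinstance(s, URIRef) and str(s).startswith(base)})
    for s in subjects:
        if s in model_nodes or str(s) in known:
            continue
        findings.append(Finding(
            "error", str(s),
            "annotation subject matches no model entity (orphan)"))

    # (b) missing-type warnings
    for a in model.agents:
        uri = URIRef(uris[entity_name([a.name]).render()])
        if (uri, RDF.type, RBMO.Agent) not in triples:
            findings.append(Finding(
                "warning", str(uri),
                f"agent {a.name!r} is not typed rbmo:Agent"))
    for r in model.rules:
        if r.label is None:
            continue
        uri = URIRef(uris[entity_name([r.label]).render()])
        if (uri, RDF.type, RBMO.Rule) not in triples:
            findings.append(Finding(
                "warning", str(uri),
                f"rule {r.label!r} is not typed rbmo:Rule"))

    # (c) typed entities detached from any model node
    for cls, what in ((RBMO.Agent, "agent"), (RBMO.Rule, "rule")):
        for s in sorted(triples.subjects(RDF.type, cls)):
            if not (isinstance(s, URIRef) and str(s).startswith(base)):
                continue
            parts = set(triples.objects(s, DCT.isPartOf))
            if not parts & model_nodes:
                findings.append(Finding(
                    "warning", str(s),
                    f"{what} is not dct:isPartOf any model-typed node"))

    # (d) hasSite / hasState targets must be declared
    agents_by_uri = {uris[entity_name([a.name]).render()]: a
                     for a in model.agents}
    sites_by_uri = {uris[entity_name([a.name, s.name]).render()]: (a, s)
                    for a in model.agents for s in a.sites}
    for s, o in sorted(triples.subject_objects(RBMO.hasSite)):
        a = agents_by_uri.get(str(s))
        if a is None:
            continue
        declared = {uris[entity_name([a.name, sd.name]).render()]
                    for sd in a.sites}
        if str(o) not in declared:
            findings.append(Finding(
                "error", str(s),
                f"rbmo:hasSite target <{o}> is not a declared site of "
                f"agent {a.name!r}"))
    for s, o in sorted(triples.subject_objects(RBMO.hasState)):
        hit = sites_by_uri.get(str(s))
        if hit is None:
            continue
        a, sd = hit
        declared = {uris[entity_name([a.name, sd.name, st.name]).render()]
                    for st in sd.states}
        if str(o) not in declared:
            findings.append(Finding(
                "error", str(s),
                f"rbmo:hasState target <{o}> is not a declared state of "
                f"site {a.name}.{sd.name}"))

    return GuidelineReport(findings)
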