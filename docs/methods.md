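# Methods

## Scope and model of the problem

`rbmannot` treats a rule-based model as three coupled artifacts: (i) the
Kappa text itself (declarations, rules, observables, variables), (ii) an
author-written RDF/Turtle document embedded in `#^` comment lines, and
(iii) a derived RDF graph in which the rules are *materialized* — rewritten
as triples using the rbmo vocabulary — and merged with (ii). Everything
downstream (contact maps, duplicate detection, consistency checking) is a
query over (iii).

## The Kappa subset

The parser accepts the KaSim-3-era line-oriented dialect: `%agent:`,
`%token:`, `%var:`, `%obs:`, `%init:` directives and rule lines with an
optional single-quoted label, `->` or `<->`, site syntax `name~state`,
`!n`, `!_` (bound, partner unknown) and `?` (unspecified), and hybrid-rule
token clauses after `|`. Deliberate behavior at the edges:

- A site mention with no binding marker is *unbound*; an omitted site is
  *unconstrained* (no site pattern is recorded at all).
- Every bond label must occur on exactly two sites of one rule side; a
  dangling bond is a parse error, not a warning.
- Bidirectional rules are kept as a single rule carrying both rates as
  opaque text: splitting would break the one-to-one mapping between rule
  labels and annotation subjects.
- `%init:` lines are retained verbatim (initial conditions are simulator
  business), and rate expressions are never evaluated.
- When agent declarations are present, patterns over declared agents are
  validated (undeclared site/state is an error); patterns naming undeclared
  agents parse permissively and are only rejected by normalization.
  Identifiers are case-sensitive.
- Unlabeled rules parse with a warning; they cannot be annotated or
  materialized because the label *is* the identity.

Serialization emits a canonical order (annotations, declarations,
variables, rules, observables, inits); parse∘serialize is the identity on
all structured fields (raw source lines are excluded from equality).

## Naming

Entity URIs come from joining declaration-path components with `:` under
the empty prefix (`:Spo0A:RR:p`); subrules append their 1-based index.
Components are percent-escaped (everything outside alphanumerics and
`_ . - ~`), which keeps the map injective — a literal `:` inside a
component cannot collide with the joiner — while every generated name
remains a valid Turtle PN_LOCAL. The empty prefix must be bound to a base
URI, either by an `@prefix : <...>` line in the annotation document or via
the `--base` option / `base=` argument.

## Annotation extraction and parsing

Extraction implements exactly the documented shell semantics: a line
participates iff its first two characters are `#^` (indented or spaced
variants are ordinary comments), and only the delimiter is removed. Turtle
parsing and serialization are delegated to rdflib; syntax errors are
mapped back to model-file line numbers through the extraction offsets. A
missing empty prefix is only an error when the document actually uses
empty-prefix names and no base was supplied, so documents written entirely
with absolute URIs still parse.

Guideline checking classifies findings as errors (orphan empty-prefix
subjects, `hasSite`/`hasState` targets that are not declared, rule labels
that are not legal local names) or warnings (agents/rules missing their
`rdf:type`, typed entities not `dct:isPartOf` a model-typed node). The
error/warning split is this package's own conformance profile — the
guidelines themselves do not rank violations. Subjects outside the model's
base namespace (e.g. helper nodes such as SBOL sequence annotations) are
exempt from the orphan check, and machine-generated predicates appearing
in hand-written annotations are accepted silently.

## Materialization schema

Node identity in the materialized graph is deterministic rather than
blank-node based: pattern nodes are `rule:lhs` / `rule:rhs` (observables:
`obs:pattern`), status nodes `rule:side:agentPosition:siteName`, and bond
URIs `rule:side:bond:label`. Deterministic skolem URIs make the output
diffable across runs and directly queryable; multiple occurrences of the
same agent in one pattern are disambiguated by their 1-based textual
position. Each status node carries exactly one `rbmo:isStatusOf` link to
its site declaration, `rbmo:internalState` when the pattern constrains the
state, and a binding status: `rbmo:UnboundState` for free sites,
`rbmo:BoundState` plus `rbmo:isBoundBy <bond>` for explicit bonds,
`rbmo:BoundState` without a bond for `!_`, and nothing for `?`. Status
nodes attach to their pattern with `dct:isPartOf`. Variables are typed
`sbo:SBO:0000002` (quantitative systems description parameter); linking a
rule to its rate variable is left to author annotations since no dedicated
predicate exists. Author triples are conserved: the merged graph is a
superset of the parsed annotation document. Normalization (the `-n` mode)
reorders pattern sites into declaration order and validates names; it is
idempotent and applied uniformly to rules, subrules and observables.

## Analyses

**Contact map.** One undirected edge per unordered (agent, site) pair
sharing a bond URI, collected from *both* rule sides — an unbinding rule
still witnesses that the contact exists — with witnessing rules kept as
provenance. Only bonds owned by `rbmo:Rule`-typed nodes count; bonds
appearing in observable patterns describe measurements, not interactions,
and including them would also break the equivalence with the brute-force
oracle computed from rules alone. The DOT renderer emits one record node
per agent (all agents in the graph, not only edge endpoints, so annotated
but unbound molecules still appear) decorated with titles, identifier
CURIEs, functions and truncated sequences from the annotations.

**Duplicates.** A join of `rbmo:Rule`-typed subjects on shared `bqbiol:is`
objects, irreflexive and symmetric-deduplicated (pairs stored with
`rule_a < rule_b`). Identity is taken literally: `bqbiol:isVersionOf`
(class membership) deliberately does not trigger duplication.

**Consistency.** `bqbiol:is` statements are strengthened to `owl:sameAs`;
equivalence classes are the connected components of the symmetric
sameAs graph; `rdf:type` assertions are pooled per class and lifted
through the transitive `rdfs:subClassOf` closure; any pooled pair of
types whose ancestors are `owl:disjointWith` is reported once per
(class, type-pair) with a proof chain — sameAs path, the two type
assertions, subclass steps, the disjointness statement — every triple of
which is present in the merged input. This is a sound but incomplete
approximation of OWL-DL reasoning (no property semantics, no complex
class expressions); `merged_graph` / `check --export-merged` produces the
input one would hand to HermiT or Pellet when completeness matters.
Ontologies are supplied as local files; nothing is fetched from the web.

## Fixtures and the random generator

The bundled two-component-system model is a synthetic reconstruction, not
a copy of any distributed example file: the biology (KinA → Spo0A
phosphotransfer consuming ATP, phosphorylated Spo0A binding an operator)
and the well-known identifiers (P16497, CHEBI:15422, GO:0000155,
GO:0008134, SO:0000167, SO:0000057) are real; the rule set, rates,
sequences and the remaining accessions are plausible stand-ins. It is
constructed to be guideline-clean and exercises every annotation pattern:
model metadata, protein/DNA/small-molecule agents, PSI-MOD state terms, an
SBOL sequence annotation helper node, a subrule (`:Phos:1`), an annotated
rate variable and an observable.

The random generator emulates small hand-written signalling models: by
default 4 agents with 1–3 sites, ≤2 states per site, 6 rules drawn from
bind/unbind/state-flip templates, two tokens with one hybrid rule, and
full annotation density (so default output is guideline-conformant;
density < 1 produces missing-type warnings but never errors). Identity
annotations draw from a built-in mock vocabulary so no network is
involved; planted artifacts (a duplicate pair sharing one identity term, a
conflict via two identity terms typed disjointly in the companion mock
ontology, one hop of sameAs plus one of subclass) are guaranteed
recoverable by construction. Generated text is a pure function of the
config. What the generator does *not* emulate: long-range rule
dependencies, token arithmetic, realistic rate structure, or annotation
errors — so passing property suites demonstrate structural correctness of
the pipeline, not robustness to malformed real-world annotation practice.

## Verification sizes and numerical choices

Property suites run over 100 generator seeds for materialization
invariants, contact-map/oracle equivalence and roundtrips, and 20–40 seeds
for planted-artifact recovery — sizes at which the whole suite completes
in seconds while covering all rule templates and annotation layouts many
times over. There is no floating-point numerics anywhere: all comparisons
are exact (string, set, graph-isomorphism). Ties and orderings are fixed
deterministically throughout (sorted subjects in reports, canonical
endpoint order in edges, BFS in sorted node order for proof chains).

## Known limitations

- The parser covers the annotation-relevant Kappa subset, not the full
  language (no algebraic rate evaluation, no perturbations, no agent
  inheritance); BioNetGen files share only the `#^` extraction step.
- Consistency checking is incomplete by design (see above).
- The materialization node-identity scheme is this package's convention;
  other tools following the same vocabulary may choose different skolem
  URIs, so graphs should be compared by content, not node names.
- Contact-map rendering assumes site names are unique within an agent
  (guaranteed by the declaration syntax) and truncates long sequences for
  legibility.
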