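# rbmannot

Semantic annotation tooling for rule-based models written in Kappa.

Rule-based languages (Kappa, BioNetGen) describe biological systems as
*agents* — molecules with named interaction *sites* that carry internal
states (e.g. phosphorylated vs unmodified) and bonds — rewritten by *rules*
at kinetic rates. The languages say nothing about what the symbols mean
biologically: `KinA(H~p)` is just text unless something records that KinA
is the sporulation kinase UniProt **P16497**, that `H` is its histidine
kinase domain, and that `~p` means a phosphorylated residue. `rbmannot`
implements a complete framework for attaching, extracting and exploiting
that information:

- **Annotation syntax.** RDF/Turtle statements are embedded in model
  comment lines beginning `#^`. Stripping the delimiter from those lines
  yields a single Turtle document, so extraction needs nothing fancier
  than `grep '^#\^' | sed 's/^#\^//'`.
- **Entity naming.** Sites, states and subrules are not top-level language
  entities, so they are addressed by Turtle prefixed names built by joining
  the declaration path with `:` under the empty prefix: the `y` state of
  `site2` of agent `A`, declared as `A(site1~u~v,site2~x~y~z)`, is
  `:A:site2:y`. Subrules get their 1-based index: `:Phos:1`. With the
  empty prefix bound to a base URI these are globally unique URIs.
- **The rbmo vocabulary** (`http://purl.org/rbm/rbmo#`): classes `Agent`,
  `Site`, `State`, `Rule`, `Observable`, `Pattern`, … and predicates
  (`hasSite`, `lhs`/`rhs`, `status`, `isBoundBy`, `internalState`, …) for
  describing models and for re-expressing the rules themselves as RDF.
- **Materialization.** `materialize_model` converts declarations, rules,
  observables and variables into RDF and merges them with the author's
  annotations into one uniform graph, with deterministic (skolem) node
  URIs. Optional normalization resolves every pattern against the
  declarations.
- **Analyses** over the merged graph: annotated **contact maps** (site–site
  binding graph, rendered as GraphViz DOT enriched with identifiers,
  functions and sequences from the annotations), **duplicate-rule
  detection** (a join on shared `bqbiol:is` identities), and
  **consistency checking** (`bqbiol:is` strengthened to `owl:sameAs`,
  types pooled per equivalence class and lifted through `rdfs:subClassOf`;
  any `owl:disjointWith` pair yields a conflict with a replayable proof
  chain; the merged graph can be exported for an external OWL reasoner).

## Worked example

The package bundles an annotated two-component-system model (sporulation
kinase KinA phosphorylates the transcription factor Spo0A, which binds a
DNA operator):

```sh
rbmannot fixtures tcs -o tcs.ka
rbmannot stats tcs.ka
```

```
agent   sites   state_space
KinA    1       2
Spo0A   2       2
Prom    1       1
Op      1       1
ATP     0       1
ADP     0       1
```

Each count is the product over sites of their internal-state counts — an
agent declared with a 2-state and a 3-state site could be used in 6
distinct ways. Extract the author's annotations, materialize the full
graph, and derive the annotated contact map:

```sh
rbmannot extract tcs.ka -o tcs.ttl        # the embedded Turtle document
rbmannot materialize --normalize tcs.ka   # rules as RDF (paper's -m/-n)
rbmannot contact-map tcs.ka               # GraphViz DOT
rbmannot check tcs.ka                     # guideline + consistency report
```

The contact map contains a single edge, `Spo0A:DNAb -- Op:tf`, witnessed
by the `TF_binding` and `Cooperative_unbinding` rules; the DOT node for
KinA carries `uniprot:P16497` and its GO molecular function pulled from
the annotations. `check` prints a TSV of guideline findings (none for the
bundled model) followed by `no conflicts found`.

The library API mirrors the CLI (`parse_model`, `entity_name`,
`materialize_model`, `contact_map`, `find_duplicate_rules`,
`check_consistency`, …); the CLI also accepts `-a` / `-m` / `-n` as
aliases for extract / materialize / normalize.

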