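# Methods

`ontoforge` implements an ontology-driven ETL method: heterogeneous input
sources (XML documents governed by an XML Schema, relational tables given
as DDL or CSV exports) are mapped, through explicitly declared rules, onto
a target OWL ontology, producing a deduplicated, logically admissible
knowledge base of individuals serialized as RDF or OWL. This note records
the model, the design choices made where the design was genuinely open,
and the limits of what the test suite demonstrates.

## The transformation model

A source is reduced to a uniform entity–attribute–relation view: an
**InputSchema** (entities with typed attributes, relations between
entities) plus a stream of **DataInstances** (one record per entity
occurrence, attribute values addressed by path expressions, links
realising the relations). Three basic rule types connect this view to the
ontology:

- `entity_rule(S, T[, c1])` — every instance of schema entity *S*
  satisfying the optional boolean condition *c1* yields one individual of
  ontology class *T*;
- `attribute_rule((S, A1), (T, A2))` — the value of attribute *A1* becomes
  the value of datatype property *A2* on that individual, with the lexical
  form preserved exactly;
- `relation_rule((S1, R1, S2), (T1, R2, T2))` — instances linked through
  schema relation *R1* yield individuals linked through object property
  *R2*.

An individual *t* is **congruent** with its source instance *s* when *t*
is obtainable from *s* by the rules, every mapped source value appears
among *t*'s assertions, and *t* participates in no consistency violation.
`check_congruence` audits this relation after a run; the test suite sweeps
it over every admitted instance.

**Transformation patterns** cover what basic rules cannot: multi-entity
templates and semantic enrichment. A pattern is a tuple ⟨S, V⟩ of axiom
statements over variables, written in a small OPPL2-like grammar (variable
declarations, `BEGIN`/`ADD`/`END;`, `instanceOf` with class expressions
limited to intersections and `some` restrictions, object/data property
additions, and `create(?base.RENDERING+_SUFFIX)` generators). A binding
attaches variables to schema entities or attribute paths. Variables
divide into *referencing* (bound to an entity that an entity rule already
transformed) and *creating* (carrying a `create()` generator, bound to an
attribute path whose value becomes the URI token, or free but typed by an
`instanceOf` statement). Statements whose terms are all fixed or fresh are
emitted on every instantiation — this is the enrichment mechanism that
lets, e.g., every chiral molecule receive the
`Molecule and has_chemical_property some Chirality` description that the
source data cannot express.

**Identity rules** decide when two individuals denote one domain entity:
for a class *C*, a declared set *IR* of datatype/object properties whose
value tuple univocally identifies an individual of *C* (or of a subclass
of *C*). Equal complete keys mean the same entity; the rule's behaviour
selects **merge** (union of assertions into the first-seen individual) or
**link** (both retained, connected with `owl:sameAs`). An individual
missing any *IR* value is *rejected-incomplete* — its source record is not
transformed, preventing inconsistency from incomplete data — unless a
pattern supplied the missing value earlier in the run. Object-valued key
components are canonicalized through the sameAs closure before comparison;
this closure-representative reading is an interpretation choice, since key
comparison over merely-linked (not merged) targets is otherwise
underdetermined.

## Execution order

One run proceeds in the fixed order: (1) entity rules produce the
candidate set I; (2) pattern statements that create new individuals run,
and those individuals join I; (3) per candidate, in order: remaining
pattern statements, attribute rules, relation rules, then identity
resolution. Because all candidates exist before step 3, relation
assertions may point forward in document order; a repair pass afterwards
rewrites assertions whose target was merged away (to the surviving URI)
and withdraws those whose target was rejected, logging each repair.
Individuals minted with identical URIs are the same individual and are
unioned on admission, independent of identity rules.

**The consistency gate.** Before admission, each candidate's whole batch
is checked structurally: class disjointness (direct and inherited through
the subclass closure), datatype-range conformance of literal lexical
forms, object-property domain/range as asserted-type checks, and
sameAs-vs-differentFrom clashes. A violating batch is discarded whole,
with the violation logged. This is a deliberately decidable core rather
than full OWL 2 DL reasoning; `invoke_reasoner_hook` shells out to an
external reasoner on the serialized knowledge base for users who need
complete DL semantics, and anonymous class-expression memberships are
preserved in the OWL output profile precisely so such a reasoner can check
them. The gate is checked per candidate (one individual plus all its
assertions from the current instance), so faulty content is discarded at
record granularity, never the whole run.

**Integration** applies the same pipeline to several sources sequentially
against one shared ontology and knowledge base. The ontology supplies the
common vocabulary (resolving naming conflicts by construction); identity
rules deduplicate or interlink equivalent individuals within and across
sources; records with conflicting identity-property values stay distinct
individuals unless they would make the knowledge base inconsistent.

## Input handling choices

- **XML Schema subset**: global/local element declarations, `complexType`
  with `sequence`, attributes, built-in simple types. `import`,
  `include`, `redefine`, `choice`, `all`, substitution groups and similar
  constructs are rejected with a named error — failing loudly beats
  silently misreading a schema. Complex-typed elements become entities;
  attributes and simple children become attributes.
- **Keyed value groups**: a complex element whose element children are all
  simple (e.g. `<property name="isChiral"><val>1</val></property>`) folds
  into its parent's attribute paths instead of becoming an entity. This is
  what makes predicate paths such as `property[@name="isChiral"]/val`
  resolvable on the owning instance, which the condition language
  requires. Nested groups (a group inside a group) do not fold and become
  entities; this is a known limitation.
- **Path language**: child steps, attribute steps (`@a`), and at most one
  `[@attr="literal"]` predicate per step. Resolution is total: a valid
  path never raises, absence is `[]`.
- **Relational input**: a `CREATE TABLE` DDL subset or a YAML table
  descriptor; tables → entities, columns → attributes, foreign keys →
  relations, a single-column primary key → the entity's key attribute.
  Composite primary keys leave no key attribute (identity must then come
  from identity rules). CSV rows follow RFC 4180 with a header row; empty
  cells are absent values, never empty-string literals.
- **Local ids / URI tokens**: the key-attribute value when declared, else
  an entity-prefixed document-order ordinal — deterministic URIs without
  needing a key. Minted URIs are `base + ClassLocalName + "/" +
  percent-encoded token`; per-class bases may instead adopt an external
  URI scheme verbatim (`adopt-external`), reproducing, e.g., UniProt
  accession URIs.
- **Condition semantics**: existential over multi-valued paths (any value
  may satisfy the comparator); value-kind coercion failure is a logged
  non-match; empty resolution is false. Ordering comparators (`lt`…`ge`)
  are accepted for numeric kinds, though equality is the only form the
  published examples exercise.
- **Mapping dialect**: a YAML document (there is no standard language for
  mappings from mixed XML/relational schemas to OWL), carrying entity /
  attribute / relation rules, pattern bindings, identity rules, external
  sameAs link declarations, and the URI policy. One instance may match
  several entity rules; each fires independently.

## Other numerical / procedural choices

- **Existential fillers**: `P some C` on an individual is grounded by
  minting one deterministic filler individual of class *C* per subject
  (token = subject token + "_" + property local name) alongside the
  anonymous-expression membership. This keeps the knowledge base ground
  and checkable without a DL reasoner.
- **RENDERING** of an individual is its URI token — the stable analogue of
  a label renderer for `create()` expressions.
- **Link topology**: each new duplicate links to its group's first-seen
  representative (a star, not a clique): the same closure at linear cost.
- **Multi-valued identity properties** are an ambiguity error and the
  record is rejected; silently picking one value would hide a data
  problem.
- **Merged-URI policy**: `first-wins` keeps the earlier individual's URI;
  `fresh-prefix` re-mints from a configured prefix plus a digest of the
  identity key, rewriting references.
- **`owl:differentFrom` emission** is off by default (it is the costly
  axiom class); when enabled it is emitted pairwise within each class
  that has an identity rule, and only between individuals with differing
  *complete* keys — beyond the keys, distinctness is unknowable.
- **Canonical serialization**: instance-level triples are emitted fully
  sorted with full URIs (prefix declarations kept as a header), so equal
  knowledge bases serialize byte-identically and
  serialize∘load∘serialize is a fixed point. RDF/XML output is produced by
  reparsing the canonical Turtle in sorted order.
- **Determinism**: the pipeline contains no sampling; the run-config seed
  exists for future tie-breaking and is threaded through the CLI so that
  repeated runs are byte-identical by construction.

## What the synthetic generators emulate — and what they do not

`synthetic_pair` emulates the integration problems the method addresses:
within-source redundancy (duplicate-rate fraction of records repeat an
earlier record's identity value), cross-source overlap (a fixed count of
identity values shared between the two sources), incomplete identity data
(missing-rate fraction of records lack the identity column but carry an
alternate column a recovery pattern can read), and conflicting
non-identity values on overlapping records. `random_project` injects two
fault classes — a non-integer value bound for an integer-ranged property,
and records routed into a class disjoint with their base class — with the
faulty record ids recorded as ground truth. All generation is
deterministic per seed, and every oracle quantity is recomputable from the
emitted bundles alone.

The defaults of the seeded integration study are two sources of 100
records each, 20 % duplication, and an overlap of 30 — sizes at which
exact brute-force oracles (union-with-dedup, group counting) are
trivially computable, which is the point of the study. What passing these
tests does **not** show: behaviour on deep XML recursion, multi-namespace
documents, schema constructs outside the supported subset, very large
sources (the identity scan is quadratic in the number of individuals per
class, fine at these scales, not tuned beyond them), or inconsistency
classes only a full DL reasoner can detect.

## Known limitations

- Relation rules fire only on relations the schema declares; transitive
  containment is not collapsed. Mappings that need an
  ancestor-containment link (e.g. gene → species across two nesting
  levels) are expressed as patterns, whose binding resolver walks the
  containment link chain bidirectionally from the anchor instance and
  takes the nearest instance of the bound entity.
- When a merge renames or removes a URI that an already-computed identity
  key referenced through an object property, the key is not recomputed;
  within a run this can only matter when per-source URI bases differ for
  the same identity rule class.
- XML namespace handling covers a single default namespace; ADL/openEHR
  archetype input, triplestore backends and a web interface are out of
  scope.
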