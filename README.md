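# ontoforge

Ontology-driven transformation and integration of heterogeneous
biomedical data — XML documents and relational/tabular exports — into
consistent, deduplicated, Linked-Open-Data-style RDF/OWL datasets.

Biomedical information about one entity (a gene, a protein, a patient
record) is scattered across resources with incompatible schemas, formats
and identifiers. Canonical format converters (XSD-to-RDF, RDB-to-RDF)
translate structure but not meaning: nothing guarantees that a "protein"
from two sources ends up described the same way, or that the generated
content is logically consistent with the domain model. `ontoforge` is for
data engineers and bioinformaticians who want to publish such sources as
five-star linked data *driven by an OWL ontology*: the ontology supplies
the vocabulary and the constraints, declared mapping rules supply the
correspondence, and the engine guarantees that only consistent,
non-redundant content is generated.

## The model

Every source is reduced to entities, attributes and relations. Three
basic rule types connect that view to the ontology:

- `entity_rule(S, T, c1)` — every instance *s* of schema entity *S*
  satisfying condition *c1* yields a congruent individual *t* of class
  *T*;
- `attribute_rule((S, A1), (T, A2))` — *A1*'s value becomes the value of
  datatype property *A2* on *t*, lexically identical;
- `relation_rule((S1, R1, S2), (T1, R2, T2))` — instances linked through
  *R1* yield individuals linked through object property *R2*.

**Transformation patterns** — templates ⟨S, V⟩ of axiom statements over
variables, in an OPPL2-like grammar — handle multi-entity mappings and
inject fixed enrichment content (e.g. typing a molecule as
`Molecule and has_chemical_property some Chirality`), including
`create(?base.RENDERING+_SUFFIX)` expressions that synthesize individuals
absent from the source. **Identity rules** `identity_rule(C, IR)` declare
the property set *IR* that univocally identifies an individual of class
*C*; equal key tuples mean the same entity, which is then *merged* or
*linked* via `owl:sameAs` depending on the rule's behaviour. Every
candidate batch passes a structural **consistency gate** (disjointness,
datatype ranges, object-property domain/range, sameAs/differentFrom
clashes) before admission; violating batches are discarded whole and
logged. See `docs/methods.md` for the full account.

## Worked example

The bundled orthologous-gene example maps an OrthoXML-style fragment
(species ⊃ database ⊃ gene) onto an orthology ontology:

```python
from ontoforge.fixtures import gene_example, run_bundle

result = run_bundle(gene_example())
gene = result.kb.individuals["http://example.org/orthdata/Gene/1"]
print("individuals:", len(result.kb.individuals))
for prop, value, _ in gene.data_assertions:
    print("data:", prop.rsplit("#")[-1], "=", value)
for prop, obj in gene.object_assertions:
    print("object:", prop.rsplit("#")[-1].rsplit("/")[-1], "->", obj)
```

prints

```
individuals: 4
data: Identifier = pyc-1
object: encodes -> http://example.org/orthdata/Protein/O17732
object: in_taxon -> http://example.org/orthdata/organisms/6239
object: contained_in -> http://example.org/orthdata/database/UniProt
```

One gene record became a `Gene` individual carrying its identifier
`pyc-1`, linked to a `Protein` individual synthesized from its `protId`
attribute, to its species (taxon 6239) through the containment chain, and
to the `UniProt` database entity — four individuals in total, each
congruent with its source record, and the whole knowledge base passes the
consistency check. An identity rule on `Gene` over
`{Identifier, in_taxon}` deduplicates the same gene arriving from other
sources.

## Command line

```bash
ontoforge fixtures gene -o projects        # write a ready-made project
ontoforge validate  -m projects/gene/manifest.yaml
ontoforge transform -m projects/gene/manifest.yaml --out gene.ttl
ontoforge integrate -m multi_source_manifest.yaml --profile owl
```

A project manifest names the schema, data, ontology, mapping and pattern
files; `transform` writes the dataset (Turtle or RDF/XML, RDF or OWL
profile), a JSON-lines decision log and a stats summary. Runs are
deterministic: repeated invocations produce byte-identical output.

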