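"""Worked examples and seeded synthetic sources for every pipeline stage.

The worked examples reproduce, end to end, the published illustrations of
the method: the OrthoXML gene fragment mapped onto an orthology ontology,
the chiral-molecule conditional rule plus enrichment pattern, the
protein–CDS–transcript pattern pair (with and without a CDS entity in the
source), and the histopathology-report pattern with CONSTANT variables.

The synthetic generators emulate the integration problems the method is
designed for — within-source redundancy, cross-source overlap, incomplete
identity data, conflicting attribute values, and logically inconsistent
content — with full ground-truth bookkeeping so every oracle quantity is
recomputable from the emitted bundles alone.  All generation is
deterministic for a fixed seed.
"""

from __future__ import annotations

import csv
import io
import random
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .mapping_rules import (
    build_identity_rules,
    build_uri_policy,
    parse_mapping_document,
    validate_mapping,
)
from .ontology_kb import load_ontology
from .pattern_engine import parse_pattern
from .schema_model import (
    load_tabular_schema,
    load_xml_schema,
    read_tabular_instances,
    read_xml_instances,
)
from .transform_engine import RunConfig, TransformResult, integrate, transform

_OWL_HEADER = """\
@prefix owl: <http://www.w3.org/2002/07/owl#> .
@prefix rdfs: <http://www.w3.org/2000/01/rdf-schema#> .
@prefix xsd: <http://www.w3.org/2001/XMLSchema#> .
"""


def golden_pattern_text(name: str) -> str:
    """Source text of one committed golden pattern file."""
    return resources.files("ontoforge.patterns").joinpath(
        f"{name}.pattern").read_text()


# ---------------------------------------------------------------------------
# Bundle plumbing
# ---------------------------------------------------------------------------

@dataclass
class ProjectBundle:
    """One self-contained transformation project, as plain documents."""
    name: str
    schema_kind: str                 # xsd | tabular
    schema_doc: str
    ontology_doc: str
    mapping_doc: str
    data: object                     # XML text, or {table: csv text}
    pattern_docs: dict = field(default_factory=dict)
    schema_keys: Optional[dict] = None
    truth: dict = field(default_factory=dict)


@dataclass
class Materialized:
    schema: object
    instances: list
    onto: object
    rules: object
    patterns: dict
    identity_rules: list
    policy: object
    validation: object


def materialize(bundle: ProjectBundle, onto=None) -> Materialized:
    """Parse a bundle's documents through the normal input path."""
    if bundle.schema_kind == "xsd":
        schema = load_xml_schema(bundle.schema_doc, keys=bundle.schema_keys)
        instances = list(read_xml_instances(bundle.data, schema,
                                            source_id=bundle.name))
    else:
        schema = load_tabular_schema(bundle.schema_doc)
        instances = list(read_tabular_instances(bundle.data, schema,
                                                source_id=bundle.name))
    if onto is None:
        onto = load_ontology(bundle.ontology_doc)
    rules = parse_mapping_document(bundle.mapping_doc)
    patterns = {name: parse_pattern(text, name)
                for name, text in bundle.pattern_docs.items()}
    validation = validate_mapping(rules, schema, onto)
    identity_rules = build_identity_rules(rules, onto)
    policy = build_uri_policy(rules, onto)
    return Materialized(schema, instances, onto, rules, patterns,
                        identity_rules, policy, validation)


def run_bundle(bundle: ProjectBundle, config: Optional[RunConfig] = None,
               **config_kwargs) -> TransformResult:
    """Materialize and transform one bundle."""
    mat = materialize(bundle)
    cfg = config or RunConfig(uri_policy=mat.policy, **config_kwargs)
    return transform(mat.schema, mat.instances, mat.rules, mat.patterns,
                     mat.identity_rules, mat.onto, cfg,
                     source_id=bundle.name)


def run_integration(bundles: list[ProjectBundle],
                    config: Optional[RunConfig] = None,
                    **config_kwargs) -> TransformResult:
    """Materialize several bundles against one shared ontology and
    integrate them into a single knowledge base."""
    onto = load_ontology(bundles[0].ontology_doc)
    sources, patterns, identity_rules = [], {}, []
    policy = None
    for bundle in bundles:
        mat = materialize(bundle, onto=onto)
        sources.append((mat.schema, mat.instances, mat.rules))
        patterns.update(mat.patterns)
        for rule in mat.identity_rules:
            if not any(r.target_class == rule.target_class and
                       r.identity_properties == rule.identity_properties
                       for r in identity_rules):
                identity_rules.append(rule)
        policy = policy or mat.policy
    cfg = config or RunConfig(uri_policy=policy, **config_kwargs)
    return integrate(sources, patterns, identity_rules, onto, cfg)


def _csv(headers: list[str], rows: list[dict]) -> str:
    buf = io.StringIO()
    writer = csv.DictWriter(buf, fieldnames=headers, lineterminator="\n")
    writer.writeheader()
    for row in rows:
        writer.writerow({h: row.get(h, "") for h in headers})
    return buf.getvalue()


# ---------------------------------------------------------------------------
# Gene worked example (OrthoXML fragment -> orthology ontology)
# ---------------------------------------------------------------------------

GENE_XSD = """\
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="species">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="database" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="gene" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:attribute name="id" type="xs:string"/>
                  <xs:attribute name="geneId" type="xs:string"/>
                  <xs:attribute name="protId" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="name" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
      <xs:attribute name="NCBITaxId" type="xs:string"/>
      <xs:attribute name="name" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
"""

GENE_XML = """\
<species NCBITaxId="6239" name="Caenorhabditis elegans">
  <database name="UniProt">
    <gene id="1" geneId="pyc-1" protId="O17732"/>
  </database>
</species>
"""

GENE_ONTOLOGY = _OWL_HEADER + """\
@prefix orth: <http://purl.org/net/orth#> .
@prefix ro: <http://purl.obolibrary.org/obo/ro#> .
@prefix ncbi: <http://purl.obolibrary.org/obo/ncbitaxon#> .
@prefix sio: <http://semanticscience.org/resource/> .

orth:Gene a owl:Class ; rdfs:label "Gene" .
orth:Protein a owl:Class ; rdfs:label "Protein" .
ncbi:organisms a owl:Class ; rdfs:label "organisms" .
sio:database a owl:Class ; rdfs:label "database" .
orth:Identifier a owl:DatatypeProperty ;
    rdfs:domain orth:Gene ; rdfs:range xsd:string .
orth:encodes a owl:ObjectProperty ;
    rdfs:domain orth:Gene ; rdfs:range orth:Protein .
ro:in_taxon a owl:ObjectProperty ;
    rdfs:domain orth:Gene ; rdfs:range ncbi:organisms .
orth:contained_in a owl:ObjectProperty ;
    rdfs:domain orth:Gene ; rdfs:range sio:database .
"""

GENE_MAPPING = """\
entity_rules:
  - {id: gene, source: gene, target: "orth:Gene"}
  - {id: species, source: species, target: "ncbi:organisms"}
  - {id: database, source: database, target: "sio:database"}
attribute_rules:
  - source: {entity: gene, path: "@geneId"}
    target: {class: "orth:Gene", property: "orth:Identifier"}
relation_rules:
  - id: contained
    source: {subject: gene, relation: "database/gene", object: database}
    target: {subject: "orth:Gene", property: "orth:contained_in",
             object: "sio:database"}
patterns:
  - pattern: gene_context
    anchor: gene
    bind:
      "?gene": {entity: gene}
      "?taxon": {entity: species}
      "?protein": {entity: gene, path: "@protId"}
identity_rules:
  - class: "orth:Gene"
    properties: ["orth:Identifier", "ro:in_taxon"]
    behaviour: merge
uri_policy:
  default_base: "http://example.org/orthdata/"
"""

GENE_CONTEXT_PATTERN = """\
?gene: INDIVIDUAL
?taxon: INDIVIDUAL
?protein: INDIVIDUAL
BEGIN
ADD ?protein instanceOf Protein,
ADD ?gene encodes ?protein,
ADD ?gene ro:in_taxon ?taxon
END;
"""


def gene_example(xml: Optional[str] = None) -> ProjectBundle:
    """The orthologous-gene worked example: a species/database/gene
    fragment mapped onto an orthology ontology, with an identity rule on
    Gene over {Identifier, in_taxon}."""
    return ProjectBundle(
        name="gene",
        schema_kind="xsd",
        schema_doc=GENE_XSD,
        schema_keys={"species": "@NCBITaxId", "database": "@name",
                     "gene": "@id"},
        ontology_doc=GENE_ONTOLOGY,
        mapping_doc=GENE_MAPPING,
        pattern_docs={"gene_context": GENE_CONTEXT_PATTERN},
        data=xml if xml is not None else GENE_XML,
    )


# ---------------------------------------------------------------------------
# Molecule worked example (conditional rule + enrichment pattern)
# ---------------------------------------------------------------------------

MOLECULE_XSD = """\
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="molecules">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="molecule" maxOccurs="unbounded">
          <xs:complexType>
            <xs:sequence>
              <xs:element name="property" maxOccurs="unbounded">
                <xs:complexType>
                  <xs:sequence>
                    <xs:element name="val" type="xs:string"/>
                  </xs:sequence>
                  <xs:attribute name="name" type="xs:string"/>
                </xs:complexType>
              </xs:element>
            </xs:sequence>
            <xs:attribute name="id" type="xs:string"/>
          </xs:complexType>
        </xs:element>
      </xs:sequence>
    </xs:complexType>
  </xs:element>
</xs:schema>
"""

MOLECULE_ONTOLOGY = _OWL_HEADER + """\
@prefix chem: <http://example.org/chem#> .

chem:Molecule a owl:Class .
chem:Chirality a owl:Class .
chem:has_chemical_property a owl:ObjectProperty ;
    rdfs:domain chem:Molecule ; rdfs:range chem:Chirality .
"""

MOLECULE_MAPPING = """\
entity_rules:
  - id: chiral
    source: molecule
    target: "chem:Molecule"
    condition: {path: 'property[@name="isChiral"]/val', op: eq,
                value: "1", kind: text}
patterns:
  - pattern: chiral_molecule
    anchor: molecule
    bind:
      "?chiralMolecule": {entity: molecule}
uri_policy:
  default_base: "http://example.org/chemdata/"
"""

#: the published pattern, following the body-text property name
CHIRAL_PATTERN = """\
?chiralMolecule: INDIVIDUAL
BEGIN
ADD ?chiralMolecule instanceOf (Molecule and has_chemical_property some Chirality)
END;
"""


def molecule_example(is_chiral: Optional[list[int]] = None) -> ProjectBundle:
    """Molecules with an isChiral property flag; only the flagged ones are
    transformed, and they receive the chirality enrichment pattern."""
    flags = is_chiral if is_chiral is not None else [1, 0, 1, 0, 0]
    parts = ["<molecules>"]
    for i, flag in enumerate(flags, start=1):
        parts.append(
            f'  <molecule id="M{i}"><property name="isChiral">'
            f"<val>{flag}</val></property></molecule>")
    parts.append("</molecules>")
    # note the schema wraps molecules in a container element, which is an
    # entity too but carries no mapping rule
    return ProjectBundle(
        name="molecule",
        schema_kind="xsd",
        schema_doc=MOLECULE_XSD,
        schema_keys={"molecule": "@id"},
        ontology_doc=MOLECULE_ONTOLOGY,
        mapping_doc=MOLECULE_MAPPING,
        pattern_docs={"chiral_molecule": CHIRAL_PATTERN},
        data="\n".join(parts),
        truth={"chiral": [f"M{i}" for i, f in enumerate(flags, 1) if f == 1],
               "achiral": [f"M{i}" for i, f in enumerate(flags, 1)
                           if f != 1]},
    )


# ---------------------------------------------------------------------------
# Protein pattern pair (with-CDS and without-CDS sources)
# ---------------------------------------------------------------------------

PROTEIN_ONTOLOGY = _OWL_HEADER + """\
@prefix bio: <http://example.org/bio#> .

bio:Polypeptide a owl:Class .
bio:CDS a owl:Class .
bio:Transcript a owl:Class .
bio:derives_from a owl:ObjectProperty ;
    rdfs:domain bio:Polypeptide ; rdfs:range bio:CDS .
bio:part_of a owl:ObjectProperty ;
    rdfs:domain bio:CDS ; rdfs:range bio:Transcript .
"""

WITH_CDS_SCHEMA = """\
CREATE TABLE transcript (id VARCHAR(16) PRIMARY KEY);
CREATE TABLE protein (ac VARCHAR(16) PRIMARY KEY);
CREATE TABLE cds (
    id VARCHAR(16) PRIMARY KEY,
    protein_ac VARCHAR(16),
    transcript_id VARCHAR(16),
    FOREIGN KEY (protein_ac) REFERENCES protein(ac),
    FOREIGN KEY (transcript_id) REFERENCES transcript(id)
);
"""

WITH_CDS_MAPPING = """\
entity_rules:
  - {id: protein, source: protein, target: "bio:Polypeptide"}
  - {id: cds, source: cds, target: "bio:CDS"}
  - {id: transcript, source: transcript, target: "bio:Transcript"}
patterns:
  - pattern: protein_with_cds
    anchor: protein
    bind:
      "?protein": {entity: protein}
      "?cds": {entity: cds}
      "?transcript": {entity: transcript}
uri_policy:
  default_base: "http://example.org/biodata/"
"""

WITHOUT_CDS_SCHEMA = """\
CREATE TABLE transcript (id VARCHAR(16) PRIMARY KEY);
CREATE TABLE protein (
    ac VARCHAR(16) PRIMARY KEY,
    transcript_id VARCHAR(16),
    FOREIGN KEY (transcript_id) REFERENCES transcript(id)
);
"""

WITHOUT_CDS_MAPPING = """\
entity_rules:
  - {id: protein, source: protein, target: "bio:Polypeptide"}
  - {id: transcript, source: transcript, target: "bio:Transcript"}
patterns:
  - pattern: protein_without_cds
    anchor: protein
    bind:
      "?protein": {entity: protein}
      "?transcript": {entity: transcript}
uri_policy:
  default_base: "http://example.org/biodata/"
"""


def protein_pattern_examples(n: int = 2) -> tuple[ProjectBundle,
                                                  ProjectBundle]:
    """Two sources storing the protein–CDS–transcript chain differently.

    The first declares a cds table; the second has a direct
    protein→transcript link and the pattern synthesizes the CDS individual
    with ``create()`` (URI token = protein token + "_CDS")."""
    accs = [f"P{i:02d}" for i in range(1, n + 1)]
    with_cds = ProjectBundle(
        name="with_cds",
        schema_kind="tabular",
        schema_doc=WITH_CDS_SCHEMA,
        ontology_doc=PROTEIN_ONTOLOGY,
        mapping_doc=WITH_CDS_MAPPING,
        pattern_docs={
            "protein_with_cds": golden_pattern_text("protein_with_cds")},
        data={
            "transcript": _csv(["id"], [{"id": f"T{i:02d}"}
                                        for i in range(1, n + 1)]),
            "protein": _csv(["ac"], [{"ac": a} for a in accs]),
            "cds": _csv(["id", "protein_ac", "transcript_id"],
                        [{"id": f"C{i:02d}", "protein_ac": f"P{i:02d}",
                          "transcript_id": f"T{i:02d}"}
                         for i in range(1, n + 1)]),
        },
        truth={"proteins": accs},
    )
    without_cds = ProjectBundle(
        name="without_cds",
        schema_kind="tabular",
        schema_doc=WITHOUT_CDS_SCHEMA,
        ontology_doc=PROTEIN_ONTOLOGY,
        mapping_doc=WITHOUT_CDS_MAPPING,
        pattern_docs={
            "protein_without_cds":
                golden_pattern_text("protein_without_cds")},
        data={
            "transcript": _csv(["id"], [{"id": f"T{i:02d}"}
                                        for i in range(1, n + 1)]),
            "protein": _csv(["ac", "transcript_id"],
                            [{"ac": f"P{i:02d}",
                              "transcript_id": f"T{i:02d}"}
                             for i in range(1, n + 1)]),
        },
        truth={"proteins": accs},
    )
    return with_cds, without_cds


# ---------------------------------------------------------------------------
# Histopathology report (CONSTANT pattern variables)
# ---------------------------------------------------------------------------

HISTO_XSD = """\
<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">
  <xs:element name="report">
    <xs:complexType>
      <xs:sequence>
        <xs:element name="finding" maxOccurs="unbounded">
          <xs:complexType>
            <xs:attribute name="id" type="xs:string"/>
          </xs:complexType>
        </xs:element>
        <xs:element name="number" type="xs:integer"/>
        <xs:element name="maxsize" type="xs:decimal"/>
      </xs:sequence>
      <xs:attribute name="id" type="xs:string"/>
    </xs:complexType>
  </xs:element>
</xs:schema>
"""

HISTO_ONTOLOGY = _OWL_HEADER + """\
@prefix hp: <http://example.org/histo#> .

hp:HistopathologyReport a owl:Class .
hp:Finding a owl:Class .
hp:hasFinding a owl:ObjectProperty ;
    rdfs:domain hp:HistopathologyReport ; rdfs:range hp:Finding .
hp:number a owl:DatatypeProperty ;
    rdfs:domain hp:HistopathologyReport ; rdfs:range xsd:integer .
hp:maxsize a owl:DatatypeProperty ;
    rdfs:domain hp:HistopathologyReport ; rdfs:range xsd:decimal .
"""

HISTO_MAPPING = """\
entity_rules:
  - {id: report, source: report, target: "hp:HistopathologyReport"}
  - {id: finding, source: finding, target: "hp:Finding"}
patterns:
  - pattern: histopathology_report
    anchor: report
    bind:
      "?histopathologyReport": {entity: report}
      "?finding": {entity: finding}
      "?size": {entity: report, path: maxsize}
      "?number": {entity: report, path: number}
uri_policy:
  default_base: "http://example.org/ehr/"
"""


def histopathology_example(number: int = 3,
                           maxsize: str = "7.5") -> ProjectBundle:
    """A histopathology report with findings, an adenoma count and the
    size of the biggest adenoma, bound to the report pattern through
    CONSTANT variables."""
    xml = (f'<report id="R1"><finding id="F1"/>'
           f"<number>{number}</number><maxsize>{maxsize}</maxsize></report>")
    return ProjectBundle(
        name="histo",
        schema_kind="xsd",
        schema_doc=HISTO_XSD,
        schema_keys={"report": "@id", "finding": "@id"},
        ontology_doc=HISTO_ONTOLOGY,
        mapping_doc=HISTO_MAPPING,
        pattern_docs={"histopathology_report":
                      golden_pattern_text("histopathology_report")},
        data=xml,
        truth={"number": str(number), "maxsize": maxsize},
    )


# ---------------------------------------------------------------------------
# Interoperability example (URI redefinition vs sameAs linkage)
# ---------------------------------------------------------------------------

INTEROP_ONTOLOGY = _OWL_HEADER + """\
@prefix up: <http://example.org/prot#> .

up:Protein a owl:Class .
up:accession a owl:DatatypeProperty ;
    rdfs:domain up:Protein ; rdfs:range xsd:string .
"""

INTEROP_SCHEMA = """\
CREATE TABLE protein (ac VARCHAR(16) PRIMARY KEY, name VARCHAR(64));
"""

_INTEROP_MAPPING_COMMON = """\
entity_rules:
  - {id: protein, source: protein, target: "up:Protein", uri_token: ac}
attribute_rules:
  - source: {entity: protein, path: ac}
    target: {class: "up:Protein", property: "up:accession"}
"""

UNIPROT_BASE = "http://purl.uniprot.org/uniprot/"


def interop_example(mode: str = "adopt",
                    accession: str = "P63284") -> ProjectBundle:
    """Two ways of linking local protein records to UniProt URIs:
    ``adopt`` redefines the minted URI to the external one, ``link`` keeps
    the local URI and emits an ``owl:sameAs`` pair to it."""
    if mode == "adopt":
        mapping = _INTEROP_MAPPING_COMMON + f"""\
uri_policy:
  default_base: "http://example.org/protdata/"
  per_class:
    "up:Protein": {{base: "{UNIPROT_BASE}", mode: adopt-external}}
"""
    elif mode == "link":
        mapping = _INTEROP_MAPPING_COMMON + f"""\
external_links:
  - {{entity: protein, base: "{UNIPROT_BASE}", token: ac}}
uri_policy:
  default_base: "http://example.org/protdata/"
"""
    else:
        raise ValueError(f"unknown interoperability mode {mode!r}")
    return ProjectBundle(
        name=f"interop-{mode}",
        schema_kind="tabular",
        schema_doc=INTEROP_SCHEMA,
        ontology_doc=INTEROP_ONTOLOGY,
        mapping_doc=mapping,
        data={"protein": _csv(["ac", "name"],
                              [{"ac": accession, "name": "ChaperoninGroEL"}])},
        truth={"external_uri": UNIPROT_BASE + accession},
    )


# ---------------------------------------------------------------------------
# Seeded synthetic source pairs (integration at scale)
# ---------------------------------------------------------------------------

@dataclass
class SyntheticSpec:
    seed: int = 0
    n_entities: int = 100
    duplicate_rate: float = 0.2
    missing_identity_rate: float = 0.0
    overlap: int = 30
    conflict_rate: float = 0.0

    def __post_init__(self):
        for name in ("duplicate_rate", "missing_identity_rate",
                     "conflict_rate"):
            val = getattr(self, name)
            if not 0.0 <= val <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {val}")
        if self.overlap > self.n_entities:
            raise ValueError("overlap cannot exceed n_entities")


SYNTH_ONTOLOGY = _OWL_HEADER + """\
@prefix sx: <http://example.org/syn#> .

sx:Protein a owl:Class .
sx:accession a owl:DatatypeProperty ;
    rdfs:domain sx:Protein ; rdfs:range xsd:string .
sx:label a owl:DatatypeProperty ;
    rdfs:domain sx:Protein ; rdfs:range xsd:string .
"""

SYNTH_SCHEMA = """\
CREATE TABLE protein (
    id VARCHAR(16) PRIMARY KEY,
    accession VARCHAR(32),
    alt_id VARCHAR(32),
    label VARCHAR(64)
);
"""

_SYNTH_MAPPING_TEMPLATE = """\
entity_rules:
  - {{id: protein, source: protein, target: "sx:Protein"}}
attribute_rules:
  - source: {{entity: protein, path: accession}}
    target: {{class: "sx:Protein", property: "sx:accession"}}
  - source: {{entity: protein, path: label}}
    target: {{class: "sx:Protein", property: "sx:label"}}
{patterns}identity_rules:
  - class: "sx:Protein"
    properties: ["sx:accession"]
    behaviour: {behaviour}
uri_policy:
  default_base: "http://example.org/syndata/"
"""

_RECOVERY_BLOCK = """\
patterns:
  - pattern: accession_recovery
    anchor: protein
    bind:
      "?rec": {entity: protein}
      "?alt": {entity: protein, path: alt_id}
"""

RECOVERY_PATTERN = """\
?rec: INDIVIDUAL
?alt: CONSTANT
BEGIN
ADD ?rec accession ?alt
END;
"""


def _synth_source(tag: str, spec: SyntheticSpec, rng: random.Random,
                  reuse_accessions: list[str], behaviour: str,
                  include_recovery: bool) -> tuple[ProjectBundle, dict]:
    n = spec.n_entities
    n_dup = round(spec.duplicate_rate * n)
    n_unique = n - n_dup
    fresh = [f"{tag}ACC{i:04d}" for i in range(n_unique - len(
        reuse_accessions))]
    uniques = list(reuse_accessions) + fresh
    rng.shuffle(uniques)
    accessions = list(uniques)
    for _ in range(n_dup):
        accessions.append(rng.choice(uniques))
    rng.shuffle(accessions)
    missing_idx = set(rng.sample(
        range(n), round(spec.missing_identity_rate * n)))
    records = []
    for i, acc in enumerate(accessions):
        rec = {"id": f"{tag}{i + 1:04d}",
               "accession": "" if i in missing_idx else acc,
               "alt_id": acc if i in missing_idx else "",
               "label": f"protein {acc}"}
        records.append(rec)
    mapping = _SYNTH_MAPPING_TEMPLATE.format(
        behaviour=behaviour,
        patterns=_RECOVERY_BLOCK if include_recovery else "")
    bundle = ProjectBundle(
        name=f"synthetic-{tag}",
        schema_kind="tabular",
        schema_doc=SYNTH_SCHEMA,
        ontology_doc=SYNTH_ONTOLOGY,
        mapping_doc=mapping,
        pattern_docs=({"accession_recovery": RECOVERY_PATTERN}
                      if include_recovery else {}),
        data={"protein": _csv(["id", "accession", "alt_id", "label"],
                              records)},
    )
    truth = {"records": records,
             "missing": sorted(r["id"] for i, r in enumerate(records)
                               if i in missing_idx),
             "accessions": accessions}
    return bundle, truth


def synthetic_pair(spec: SyntheticSpec, behaviour: str = "merge",
                   include_recovery: bool = False
                   ) -> tuple[ProjectBundle, ProjectBundle, dict]:
    """Two tabular protein sources sharing one ontology, with controlled
    within-source duplication, cross-source overlap, missing identity
    values and conflicting labels; full ground truth is returned."""
    rng = random.Random(spec.seed)
    a_bundle, a_truth = _synth_source("A", spec, rng, [], behaviour,
                                      include_recovery)
    a_uniques = sorted(set(a_truth["accessions"]))
    shared = rng.sample(a_uniques, min(spec.overlap, len(a_uniques)))
    b_bundle, b_truth = _synth_source("B", spec, rng, shared, behaviour,
                                      include_recovery)
    # conflicting labels on some overlapping records
    n_conflict = round(spec.conflict_rate * len(shared))
    conflicted = set(shared[:n_conflict])
    if conflicted:
        rows = []
        for rec in b_truth["records"]:
            if rec["accession"] in conflicted:
                rec = dict(rec, label=f"variant {rec['accession']}")
            rows.append(rec)
        b_truth["records"] = rows
        b_bundle.data = {"protein": _csv(
            ["id", "accession", "alt_id", "label"], rows)}
    truth = {
        "a": a_truth, "b": b_truth,
        "shared_accessions": sorted(shared),
        "conflicted_accessions": sorted(conflicted),
        "expected_merged_count": len(
            {r["accession"] for r in a_truth["records"] + b_truth["records"]
             if r["accession"]}),
        "expected_rejected": len(a_truth["missing"]) +
        len(b_truth["missing"]),
    }
    truth["expected_sameas_pairs"] = sum(
        c - 1 for c in _group_counts(truth).values())
    return a_bundle, b_bundle, truth


def _group_counts(truth: dict) -> dict[str, int]:
    counts: dict[str, int] = {}
    for rec in truth["a"]["records"] + truth["b"]["records"]:
        if rec["accession"]:
            counts[rec["accession"]] = counts.get(rec["accession"], 0) + 1
    return counts


# ---------------------------------------------------------------------------
# Random fault-injected projects (consistency-gate exercise)
# ---------------------------------------------------------------------------

FAULT_ONTOLOGY = _OWL_HEADER + """\
@prefix fx: <http://example.org/fault#> .

fx:ItemA a owl:Class .
fx:ItemB a owl:Class .
fx:ItemA owl:disjointWith fx:ItemB .
fx:name a owl:DatatypeProperty ;
    rdfs:domain fx:ItemA ; rdfs:range xsd:string .
fx:size a owl:DatatypeProperty ;
    rdfs:domain fx:ItemA ; rdfs:range xsd:integer .
fx:flagval a owl:DatatypeProperty ;
    rdfs:domain fx:ItemA ; rdfs:range xsd:string .
"""

FAULT_SCHEMA = """\
CREATE TABLE item (
    id VARCHAR(16) PRIMARY KEY,
    name VARCHAR(64),
    measure VARCHAR(16),
    bad VARCHAR(4)
);
"""

FAULT_MAPPING = """\
entity_rules:
  - {id: item, source: item, target: "fx:ItemA"}
attribute_rules:
  - source: {entity: item, path: name}
    target: {class: "fx:ItemA", property: "fx:name"}
patterns:
  - pattern: size_pattern
    anchor: item
    bind:
      "?item": {entity: item}
      "?v": {entity: item, path: measure}
  - pattern: disjoint_pattern
    anchor: item
    bind:
      "?item": {entity: item}
      "?flag": {entity: item, path: bad}
uri_policy:
  default_base: "http://example.org/faultdata/"
"""

SIZE_PATTERN = """\
?item: INDIVIDUAL
?v: CONSTANT
BEGIN
ADD ?item size ?v
END;
"""

DISJOINT_PATTERN = """\
?item: INDIVIDUAL
?flag: CONSTANT
BEGIN
ADD ?item flagval ?flag,
ADD ?item instanceOf ItemB
END;
"""


def random_project(seed: int) -> ProjectBundle:
    """One small tabular project with seeded fault injection.

    Each record is clean, carries a non-integer value destined for an
    integer-ranged property (datatype-range fault), or is routed into a
    class disjoint with its base class (disjointness fault).  The faulty
    record ids are recorded as ground truth."""
    rng = random.Random(seed)
    n = rng.randint(8, 15)
    rows, faulty = [], []
    for i in range(1, n + 1):
        rid = f"I{i:03d}"
        fault = rng.choice(["none", "none", "none", "datatype", "disjoint"])
        row = {"id": rid, "name": f"item {rid}",
               "measure": str(rng.randint(1, 99)), "bad": ""}
        if fault == "datatype":
            row["measure"] = "not-a-number"
            faulty.append(rid)
        elif fault == "disjoint":
            row["bad"] = "1"
            faulty.append(rid)
        rows.append(row)
    return ProjectBundle(
        name=f"fault-{seed}",
        schema_kind="tabular",
        schema_doc=FAULT_SCHEMA,
        ontology_doc=FAULT_ONTOLOGY,
        mapping_doc=FAULT_MAPPING,
        pattern_docs={"size_pattern": SIZE_PATTERN,
                      "disjoint_pattern": DISJOINT_PATTERN},
        data={"item": _csv(["id", "name", "measure", "bad"], rows)},
        truth={"faulty": faulty, "clean": [r["id"] for r in rows
                                           if r["id"] not in faulty],
               "n": n},
    )
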