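"""Unit tests for the ontology model, URI policy, KB and serialization."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ontoforge.errors import OntoforgeError, SerializationRefusedError, \
    UnknownTermError
from ontoforge.fixtures import GENE_ONTOLOGY, _OWL_HEADER
from ontoforge.ontology_kb import (
    AxiomBatch,
    ClassRef,
    Individual,
    KnowledgeBase,
    URIPolicy,
    XSD_INTEGER,
    XSD_STRING,
    assert_axioms,
    check_consistency,
    load_ontology,
    mint_uri,
    parse_kb,
    serialize_kb,
)

EX = "http://example.org/t#"

SMALL_ONTOLOGY = _OWL_HEADER + f"""\
@prefix ex: <{EX}> .
ex:A a owl:Class .
ex:B a owl:Class .
ex:Sub a owl:Class ; rdfs:subClassOf ex:A .
ex:A owl:disjointWith ex:B .
ex:count a owl:DatatypeProperty ; rdfs:domain ex:A ; rdfs:range xsd:integer .
ex:knows a owl:ObjectProperty ; rdfs:domain ex:A ; rdfs:range ex:B .
"""


@pytest.fixture(scope="module")
def onto():
    return load_ontology(SMALL_ONTOLOGY)


def make_kb(onto):
    return KnowledgeBase(ontology=onto)


def make_ind(uri, cls, token="t"):
    ind = Individual(uri=uri, token=token, provenance=[("test", "e", "1")])
    ind.add_class(cls)
    return ind


class TestLoadOntology:
    def test_fixture_ontology_terms(self):
        model = load_ontology(GENE_ONTOLOGY)
        names = {c.rsplit("#", 1)[-1].rsplit("/", 1)[-1]
                 for c in model.classes}
        assert {"Gene", "Protein", "organisms", "database"} <= names
        assert any(p.endswith("in_taxon") for p in model.object_properties)

    def test_subclass_and_disjointness_capture(self, onto):
        assert EX + "A" in onto.ancestors(EX + "Sub")
        assert frozenset((EX + "A", EX + "B")) in onto.disjointness

    def test_empty_document_warns(self):
        model = load_ontology("")
        assert not model.classes
        assert any("empty" in w for w in model.warnings)

    @pytest.mark.parametrize("k", [1, 7])
    def test_generated_class_count(self, k):
        doc = _OWL_HEADER + f"@prefix g: <{EX}> .\n" + "\n".join(
            f"g:C{i} a owl:Class ." for i in range(k))
        assert len(load_ontology(doc).classes) == k

    def test_unparseable_document_is_format_error(self):
        with pytest.raises(OntoforgeError, match="parse"):
            load_ontology("this is not turtle @@@")


class TestMintUri:
    def test_adopt_external_reproduces_uniprot_uri(self):
        policy = URIPolicy(
            default_base="http://example.org/d/",
            per_class_base={EX + "A": "http://purl.uniprot.org/uniprot/"},
            mode={EX + "A": "adopt-external"})
        uri = mint_uri(policy, ClassRef(EX + "A"), "P63284")
        assert uri == "http://purl.uniprot.org/uniprot/P63284"

    def test_mint_local_shape_and_encoding(self):
        policy = URIPolicy(default_base="http://example.org/d/")
        uri = mint_uri(policy, ClassRef(EX + "Gene"), "pyc-1|6239")
        assert uri == "http://example.org/d/Gene/pyc-1%7C6239"

    def test_empty_token_is_an_error(self):
        with pytest.raises(OntoforgeError):
            mint_uri(URIPolicy(), ClassRef(EX + "A"), "")

    def test_distinct_tokens_distinct_uris(self):
        policy = URIPolicy(default_base="http://example.org/d/")
        tokens = [f"tok{i}|{i % 7}" for i in range(1000)]
        uris = {mint_uri(policy, ClassRef(EX + "A"), t) for t in tokens}
        assert len(uris) == 1000

    @settings(derandomize=True, max_examples=50)
    @given(st.text(min_size=1, max_size=20))
    def test_minting_is_deterministic_and_absolute_http(self, token):
        policy = URIPolicy(default_base="http://example.org/d/")
        u1 = mint_uri(policy, ClassRef(EX + "A"), token)
        u2 = mint_uri(policy, ClassRef(EX + "A"), token)
        assert u1 == u2
        assert u1.startswith("http://")
        assert " " not in u1


class TestAssertAxioms:
    def test_idempotence(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        batch = AxiomBatch(new_individuals=[ind],
                           assertions=[("data", EX + "i/1", EX + "count",
                                        "3", XSD_INTEGER)])
        assert_axioms(kb, batch)
        sig = kb.signature()
        assert_axioms(kb, batch)
        assert kb.signature() == sig

    def test_batch_sizes(self, onto):
        kb = make_kb(onto)
        i1 = make_ind(EX + "i/1", ClassRef(EX + "A"))
        i2 = make_ind(EX + "i/2", ClassRef(EX + "B"))
        batch = AxiomBatch(
            new_individuals=[i1, i2],
            assertions=[("data", EX + "i/1", EX + "count", "1", XSD_INTEGER),
                        ("data", EX + "i/1", EX + "count", "2", XSD_INTEGER),
                        ("object", EX + "i/1", EX + "knows", EX + "i/2")])
        assert_axioms(kb, batch)
        assert len(kb.individuals) == 2
        total = sum(len(i.data_assertions) + len(i.object_assertions)
                    for i in kb.individuals.values())
        assert total == 3

    def test_unknown_property_named_in_error(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        batch = AxiomBatch(new_individuals=[ind],
                           assertions=[("data", EX + "i/1", EX + "nope",
                                        "x", XSD_STRING)])
        with pytest.raises(UnknownTermError, match="nope"):
            assert_axioms(kb, batch)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_order_independence(self, onto, seed):
        """Applying a batch sequence in any order equals applying the
        set-union at once."""
        rng = random.Random(seed)
        items = []
        for i in range(10):
            ind = make_ind(EX + f"i/{i % 4}",
                           ClassRef(EX + ("A" if i % 2 else "Sub")))
            ind.add_data(EX + "count", str(i % 3), XSD_INTEGER)
            items.append(AxiomBatch(new_individuals=[ind]))
        kb1 = make_kb(onto)
        for b in items:
            assert_axioms(kb1, b)
        kb2 = make_kb(onto)
        shuffled = list(items)
        rng.shuffle(shuffled)
        for b in shuffled:
            assert_axioms(kb2, b)
        assert kb1.signature() == kb2.signature()


class TestCheckConsistency:
    def test_disjoint_classes_direct_and_inherited(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "Sub"))   # Sub <= A
        ind.add_class(ClassRef(EX + "B"))
        assert_axioms(kb, AxiomBatch(new_individuals=[ind]))
        report = check_consistency(kb)
        assert [v.kind for v in report.violations] == ["disjointness"]

    def test_datatype_range_violation(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        ind.add_data(EX + "count", "not-an-int", XSD_INTEGER)
        assert_axioms(kb, AxiomBatch(new_individuals=[ind]))
        report = check_consistency(kb)
        assert [v.kind for v in report.violations] == ["datatype-range"]

    def test_sameas_vs_differentfrom_clash(self, onto):
        kb = make_kb(onto)
        for i in (1, 2):
            assert_axioms(kb, AxiomBatch(new_individuals=[
                make_ind(EX + f"i/{i}", ClassRef(EX + "A"))]))
        kb.same_as.append(frozenset((EX + "i/1", EX + "i/2")))
        kb.different_from.append(frozenset((EX + "i/1", EX + "i/2")))
        report = check_consistency(kb)
        assert [v.kind for v in report.violations] == \
            ["sameas-vs-differentfrom"]

    def test_object_domain_and_range_checks(self, onto):
        kb = make_kb(onto)
        bad = make_ind(EX + "i/1", ClassRef(EX + "B"))   # B, not domain A
        tgt = make_ind(EX + "i/2", ClassRef(EX + "A"))   # A, not range B
        bad.add_object(EX + "knows", EX + "i/2")
        assert_axioms(kb, AxiomBatch(new_individuals=[bad, tgt]))
        kinds = sorted(v.kind for v in check_consistency(kb).violations)
        assert kinds == ["object-domain", "object-range"]

    def test_candidate_checked_without_mutation(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        ind.add_class(ClassRef(EX + "B"))
        report = check_consistency(kb, AxiomBatch(new_individuals=[ind]))
        assert not report.empty
        assert not kb.individuals   # KB untouched

    def test_monotonicity_on_admissible_union(self, onto):
        """If KB plus batch is admissible then KB alone is admissible."""
        kb = make_kb(onto)
        assert_axioms(kb, AxiomBatch(new_individuals=[
            make_ind(EX + "i/1", ClassRef(EX + "A"))]))
        batch = AxiomBatch(new_individuals=[
            make_ind(EX + "i/2", ClassRef(EX + "B"))])
        assert check_consistency(kb, batch).empty
        assert check_consistency(kb).empty


class TestSerialization:
    def test_empty_kb_is_prefixes_only(self, onto):
        doc = serialize_kb(make_kb(onto), "turtle", "rdf")
        lines = [ln for ln in doc.splitlines() if ln.strip()]
        assert all(ln.startswith("@prefix") for ln in lines)

    def test_round_trip_is_fixed_point(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        ind.add_data(EX + "count", "5", XSD_INTEGER)
        assert_axioms(kb, AxiomBatch(new_individuals=[ind]))
        doc1 = serialize_kb(kb, "turtle", "owl")
        doc2 = serialize_kb(parse_kb(doc1, onto), "turtle", "owl")
        assert doc1 == doc2

    def test_equal_kbs_serialize_byte_identically(self, onto):
        def build(order):
            kb = make_kb(onto)
            for i in order:
                ind = make_ind(EX + f"i/{i}", ClassRef(EX + "A"))
                ind.add_data(EX + "count", str(i), XSD_INTEGER)
                assert_axioms(kb, AxiomBatch(new_individuals=[ind]))
            return kb
        assert serialize_kb(build([1, 2, 3]), "turtle", "rdf") == \
            serialize_kb(build([3, 1, 2]), "turtle", "rdf")

    def test_all_subjects_absolute_http(self, gene_result):
        doc = serialize_kb(gene_result.kb, "turtle", "rdf")
        for line in doc.splitlines():
            if line.startswith("<"):
                assert line.startswith("<http")

    def test_violations_refuse_serialization(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        ind.add_data(EX + "count", "x", XSD_INTEGER)
        assert_axioms(kb, AxiomBatch(new_individuals=[ind]))
        with pytest.raises(SerializationRefusedError):
            serialize_kb(kb, "turtle", "rdf")
        assert "count" in serialize_kb(kb, "turtle", "rdf", override=True)

    def test_rdfxml_reloads_to_equal_kb(self, onto):
        kb = make_kb(onto)
        ind = make_ind(EX + "i/1", ClassRef(EX + "A"))
        ind.add_data(EX + "count", "5", XSD_INTEGER)
        assert_axioms(kb, AxiomBatch(new_individuals=[ind]))
        xml = serialize_kb(kb, "rdfxml", "rdf")
        assert parse_kb(xml, onto, "rdfxml").signature() == kb.signature()
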