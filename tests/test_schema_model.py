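"""Unit tests for the uniform schema/instance model and its readers."""

import random

import pytest
from hypothesis import given, settings, strategies as st

from ontoforge.errors import (
    CoercionError,
    DanglingReferenceError,
    PathSyntaxError,
    StrictReadError,
    UnsupportedConstructError,
    XmlParseError,
)
from ontoforge.fixtures import GENE_XML, GENE_XSD, gene_example
from ontoforge.schema_model import (
    DataInstance,
    load_tabular_schema,
    load_xml_schema,
    parse_path,
    read_tabular_instances,
    read_xml_instances,
    resolve_path,
)


# ---------------------------------------------------------------------------
# XML Schema reading
# ---------------------------------------------------------------------------

class TestLoadXmlSchema:
    def test_orthoxml_subset_structure(self):
        schema = load_xml_schema(GENE_XSD)
        assert set(schema.entities) == {"species", "database", "gene"}
        gene = schema.entities["gene"]
        assert set(gene.attributes) == {"@id", "@geneId", "@protId"}
        rels = {(r.source_entity, r.target_entity, r.realization)
                for r in schema.relations.values()}
        assert rels == {("species", "database", "xml-containment"),
                        ("database", "gene", "xml-containment")}

    def test_single_empty_complex_element(self):
        xsd = ('<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">'
               '<xs:element name="thing"><xs:complexType/></xs:element>'
               "</xs:schema>")
        schema = load_xml_schema(xsd)
        assert len(schema.entities) == 1
        assert not schema.entities["thing"].attributes
        assert not schema.relations

    @pytest.mark.parametrize("n_entities", [2, 5, 9])
    def test_random_tree_entity_and_relation_counts(self, n_entities):
        """A generated XSD nesting E complex elements as a tree must yield
        E entities and E-1 containment relations."""
        rng = random.Random(n_entities)
        children: dict[int, list[int]] = {i: [] for i in range(n_entities)}
        for i in range(1, n_entities):
            children[rng.randrange(i)].append(i)

        def element(i):
            inner = "".join(element(c) for c in children[i])
            return (f'<xs:element name="e{i}"><xs:complexType>'
                    f"<xs:sequence>{inner}</xs:sequence>"
                    f'<xs:attribute name="a" type="xs:string"/>'
                    f"</xs:complexType></xs:element>")

        xsd = ('<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">'
               + element(0) + "</xs:schema>")
        schema = load_xml_schema(xsd)
        assert len(schema.entities) == n_entities
        assert len(schema.relations) == n_entities - 1

    def test_malformed_document_names_parse_error(self):
        with pytest.raises(XmlParseError):
            load_xml_schema("<xs:schema><unclosed>")

    @pytest.mark.parametrize("construct", ["import", "redefine", "choice"])
    def test_unsupported_constructs_rejected_by_name(self, construct):
        xsd = (f'<xs:schema xmlns:xs="http://www.w3.org/2001/XMLSchema">'
               f"<xs:{construct}/>"
               f'<xs:element name="x"><xs:complexType/></xs:element>'
               f"</xs:schema>")
        with pytest.raises(UnsupportedConstructError, match=construct):
            load_xml_schema(xsd)


# ---------------------------------------------------------------------------
# Tabular schema reading
# ---------------------------------------------------------------------------

PROTEIN_GENE_DDL = """\
CREATE TABLE protein (ac VARCHAR(10) PRIMARY KEY, name VARCHAR(64));
CREATE TABLE gene (
    id VARCHAR(10) PRIMARY KEY,
    protein_ac VARCHAR(10),
    FOREIGN KEY (protein_ac) REFERENCES protein(ac)
);
"""


class TestLoadTabularSchema:
    def test_two_tables_one_foreign_key(self):
        schema = load_tabular_schema(PROTEIN_GENE_DDL)
        assert set(schema.entities) == {"protein", "gene"}
        assert schema.entities["protein"].key_attribute == "ac"
        (rel,) = schema.relations.values()
        assert (rel.source_entity, rel.target_entity,
                rel.realization) == ("gene", "protein", "foreign-key")

    def test_composite_primary_key_leaves_no_key_attribute(self):
        ddl = ("CREATE TABLE pair (a INT, b INT, PRIMARY KEY (a, b));")
        schema = load_tabular_schema(ddl)
        assert schema.entities["pair"].key_attribute is None
        assert any("composite" in w for w in schema.warnings)

    def test_dangling_foreign_key_is_an_error(self):
        ddl = ("CREATE TABLE gene (id INT PRIMARY KEY, x INT, "
               "FOREIGN KEY (x) REFERENCES nowhere(id));")
        with pytest.raises(DanglingReferenceError, match="nowhere"):
            load_tabular_schema(ddl)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_generated_descriptor_counts(self, seed):
        """T generated tables with F foreign keys must produce a schema
        with T entities and F relations."""
        rng = random.Random(seed)
        n_tables = rng.randint(3, 7)
        stmts, n_fk = [], 0
        for t in range(n_tables):
            cols = [f"c{j} INT" for j in range(rng.randint(1, 3))]
            cols.insert(0, "id INT PRIMARY KEY")
            if t > 0 and rng.random() < 0.7:
                ref = rng.randrange(t)
                cols.append(f"FOREIGN KEY (c0) REFERENCES t{ref}(id)")
                n_fk += 1
            stmts.append(f"CREATE TABLE t{t} ({', '.join(cols)});")
        schema = load_tabular_schema("\n".join(stmts))
        assert len(schema.entities) == n_tables
        assert len(schema.relations) == n_fk

    def test_yaml_descriptor_equivalent(self):
        schema = load_tabular_schema(
            "tables:\n"
            "  protein:\n"
            "    columns: {ac: text}\n"
            "    primary_key: ac\n"
            "  gene:\n"
            "    columns: {id: text, protein_ac: text}\n"
            "    primary_key: id\n"
            "    foreign_keys:\n"
            "      - {column: protein_ac, references: protein}\n")
        assert set(schema.entities) == {"protein", "gene"}
        assert len(schema.relations) == 1


# ---------------------------------------------------------------------------
# XML instance reading
# ---------------------------------------------------------------------------

class TestReadXmlInstances:
    def test_gene_fragment_instances_and_links(self, gene_bundle):
        schema = load_xml_schema(GENE_XSD, keys=gene_bundle.schema_keys)
        insts = list(read_xml_instances(GENE_XML, schema))
        assert [i.entity for i in insts] == ["species", "database", "gene"]
        gene = insts[2]
        assert resolve_path(gene, "@protId") == ["O17732"]
        assert resolve_path(gene, "@geneId") == ["pyc-1"]
        # containment links connect gene to its species through the chain
        species, database = insts[0], insts[1]
        assert ("species/database", database.local_id) in species.links
        assert ("database/gene", gene.local_id) in database.links

    def test_empty_document_body_yields_empty_stream(self):
        schema = load_xml_schema(GENE_XSD)
        assert list(read_xml_instances("<container/>", schema)) == []

    @pytest.mark.parametrize("n", [1, 4, 10])
    def test_generated_document_instance_count(self, n, gene_bundle):
        schema = load_xml_schema(GENE_XSD, keys=gene_bundle.schema_keys)
        genes = "".join(f'<gene id="{i}" geneId="g{i}"/>' for i in range(n))
        doc = (f'<species NCBITaxId="1"><database name="db">{genes}'
               "</database></species>")
        insts = [i for i in read_xml_instances(doc, schema)
                 if i.entity == "gene"]
        assert len(insts) == n
        assert [i.local_id for i in insts] == [str(i) for i in range(n)]

    def test_undeclared_element_strict_vs_lenient(self):
        schema = load_xml_schema(GENE_XSD)
        doc = "<species><intruder/></species>"
        with pytest.raises(StrictReadError, match="intruder"):
            list(read_xml_instances(doc, schema, strict=True))
        insts = list(read_xml_instances(doc, schema, strict=False))
        assert [i.entity for i in insts] == ["species"]

    def test_two_reads_yield_identical_sequences(self):
        schema = load_xml_schema(GENE_XSD)
        one = list(read_xml_instances(GENE_XML, schema))
        two = list(read_xml_instances(GENE_XML, schema))
        assert [(i.entity, i.local_id, i.attribute_values, i.links)
                for i in one] == \
            [(i.entity, i.local_id, i.attribute_values, i.links)
             for i in two]


# ---------------------------------------------------------------------------
# Tabular instance reading
# ---------------------------------------------------------------------------

class TestReadTabularInstances:
    def test_foreign_key_produces_link(self):
        schema = load_tabular_schema(PROTEIN_GENE_DDL)
        rows = {"protein": "ac,name\nP1,alpha\n",
                "gene": "id,protein_ac\nG1,P1\n"}
        insts = list(read_tabular_instances(rows, schema))
        assert len(insts) == 2
        gene = [i for i in insts if i.entity == "gene"][0]
        assert gene.links == [("gene.protein_ac", "P1")]

    def test_empty_cell_is_absent_not_empty_literal(self):
        schema = load_tabular_schema(PROTEIN_GENE_DDL)
        rows = {"gene": "id,protein_ac\nG1,\n"}
        (gene,) = read_tabular_instances(rows, schema)
        assert gene.links == []
        assert "protein_ac" not in gene.attribute_values

    def test_value_kind_violation_names_row_and_column(self):
        schema = load_tabular_schema(
            "CREATE TABLE m (id INT PRIMARY KEY, size INT);")
        rows = {"m": "id,size\n1,big\n"}
        with pytest.raises(CoercionError, match="row 1.*'size'"):
            list(read_tabular_instances(rows, schema))

    @pytest.mark.parametrize("seed", [0, 3])
    def test_duplicate_primary_keys_strict_vs_lenient(self, seed):
        rng = random.Random(seed)
        n = rng.randint(5, 12)
        ids = [f"r{rng.randrange(n // 2)}" for _ in range(n)]
        n_dups = n - len(set(ids))   # brute-force duplicate scan
        rows = {"protein": "ac,name\n" +
                "".join(f"{i},x\n" for i in ids)}
        schema = load_tabular_schema(PROTEIN_GENE_DDL)
        if n_dups:
            with pytest.raises(StrictReadError, match="duplicate"):
                list(read_tabular_instances(rows, schema, strict=True))
        lenient = list(read_tabular_instances(rows, schema, strict=False))
        assert len(lenient) == n - n_dups


# ---------------------------------------------------------------------------
# Path expressions
# ---------------------------------------------------------------------------

class TestResolvePath:
    def make_molecule(self):
        inst = DataInstance(entity="molecule", local_id="M1")
        inst.add_value("property[0]/@name", "isChiral")
        inst.add_value("property[0]/val", "1")
        inst.add_value("property[1]/@name", "weight")
        inst.add_value("property[1]/val", "42.0")
        return inst

    def test_predicate_path_selects_correlated_value(self):
        inst = self.make_molecule()
        assert resolve_path(inst, 'property[@name="isChiral"]/val') == ["1"]
        assert resolve_path(inst, 'property[@name="weight"]/val') == ["42.0"]

    def test_plain_path_collects_all_occurrences_in_order(self):
        inst = self.make_molecule()
        assert resolve_path(inst, "property/val") == ["1", "42.0"]

    def test_attribute_step(self):
        inst = DataInstance(entity="gene", local_id="1")
        inst.add_value("@geneId", "pyc-1")
        assert resolve_path(inst, "@geneId") == ["pyc-1"]

    def test_absence_is_empty_list_not_error(self):
        inst = DataInstance(entity="gene", local_id="1")
        assert resolve_path(inst, 'property[@name="x"]/val') == []
        assert resolve_path(inst, "@anything") == []

    @pytest.mark.parametrize("bad", ["", "a//b", "a[", '@x[@y="1"]',
                                     "@a/b"])
    def test_invalid_paths_raise_syntax_error(self, bad):
        with pytest.raises(PathSyntaxError):
            parse_path(bad)

    @settings(derandomize=True, max_examples=50)
    @given(st.lists(st.sampled_from(["gene", "val", "property", "name"]),
                    min_size=1, max_size=3),
           st.booleans())
    def test_valid_paths_never_raise_on_any_instance(self, names, attr_last):
        """Path totality: resolution of a syntactically valid path is
        always a list, never an exception."""
        steps = list(names)
        if attr_last:
            steps[-1] = "@" + steps[-1]
        path = "/".join(steps)
        inst = DataInstance(entity="e", local_id="1")
        inst.add_value("gene", "x")
        assert isinstance(resolve_path(inst, path), list)
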