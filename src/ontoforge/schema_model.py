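"""Uniform entity–attribute–relation view of input schemas and their records.

Heterogeneous sources (XML documents governed by an XML Schema, relational
tables given as DDL or a declarative descriptor) are reduced to one model:

* an :class:`InputSchema` holds named entities, their typed attributes and
  the relations between entities;
* a :class:`DataInstance` is one record of one entity, carrying literal
  attribute values addressed by path expressions, plus links realising the
  schema's relations.

Attribute paths form a tiny language: child steps (``val``), attribute
steps (``@name``) and at most one ``[@attr="literal"]`` predicate per step,
e.g. ``property[@name="isChiral"]/val``.  Nested "keyed value group"
elements (a complex XML element whose element children are all simple, such
as ``<property name="isChiral"><val>1</val></property>``) are folded into
the owning entity's attribute paths rather than becoming entities of their
own, which is what makes such predicate paths resolvable on the owner.
"""

from __future__ import annotations

import csv
import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterator, Optional

from lxml import etree

from .errors import (
    CoercionError,
    DanglingReferenceError,
    PathSyntaxError,
    StrictReadError,
    UnsupportedConstructError,
    XmlParseError,
)

logger = logging.getLogger("ontoforge")

VALUE_KINDS = ("text", "integer", "decimal", "boolean")

XSD_NS = "http://www.w3.org/2001/XMLSchema"

#: XSD built-in simple types mapped onto the four supported value kinds.
_XSD_KIND = {
    "string": "text", "normalizedString": "text", "token": "text",
    "anyURI": "text", "ID": "text", "IDREF": "text", "NMTOKEN": "text",
    "date": "text", "dateTime": "text",
    "int": "integer", "integer": "integer", "long": "integer",
    "short": "integer", "byte": "integer", "nonNegativeInteger": "integer",
    "positiveInteger": "integer", "unsignedInt": "integer",
    "unsignedLong": "integer",
    "decimal": "decimal", "float": "decimal", "double": "decimal",
    "boolean": "boolean",
}


def coerce_value(kind: str, text: str):
    """Coerce a lexical value to its declared kind; raise CoercionError."""
    try:
        if kind == "integer":
            return int(text)
        if kind == "decimal":
            return float(text)
        if kind == "boolean":
            if text in ("true", "1"):
                return True
            if text in ("false", "0"):
                return False
            raise ValueError(text)
        return text
    except ValueError as exc:
        raise CoercionError(f"value {text!r} is not a valid {kind}") from exc


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SchemaAttribute:
    owner: str                 # entity name
    path: str                  # attribute path expression relative to owner
    value_kind: str = "text"

    def __post_init__(self):
        if not self.path:
            raise ValueError("attribute path must be non-empty")
        if self.value_kind not in VALUE_KINDS:
            raise ValueError(f"unknown value kind {self.value_kind!r}")


@dataclass
class SchemaEntity:
    name: str
    attributes: dict[str, SchemaAttribute] = field(default_factory=dict)
    key_attribute: Optional[str] = None

    def add_attribute(self, attr: SchemaAttribute) -> None:
        if attr.path in self.attributes:
            raise ValueError(
                f"duplicate attribute {attr.path!r} in entity {self.name!r}")
        self.attributes[attr.path] = attr


@dataclass(frozen=True)
class SchemaRelation:
    name: str
    source_entity: str
    target_entity: str
    realization: str   # xml-containment | foreign-key | reference-attribute


@dataclass
class InputSchema:
    name: str
    entities: dict[str, SchemaEntity] = field(default_factory=dict)
    relations: dict[str, SchemaRelation] = field(default_factory=dict)
    kind: str = "xml"          # xml | relational
    warnings: list[str] = field(default_factory=list)

    def add_entity(self, entity: SchemaEntity) -> None:
        if entity.name in self.entities:
            raise ValueError(f"duplicate entity {entity.name!r}")
        self.entities[entity.name] = entity

    def add_relation(self, rel: SchemaRelation) -> None:
        for end in (rel.source_entity, rel.target_entity):
            if end not in self.entities:
                raise DanglingReferenceError(
                    f"relation {rel.name!r} references unknown entity {end!r}")
        if rel.realization == "xml-containment" and self.kind != "xml":
            raise ValueError("xml-containment relation in non-XML schema")
        if rel.realization == "foreign-key" and self.kind != "relational":
            raise ValueError("foreign-key relation in non-relational schema")
        self.relations[rel.name] = rel


@dataclass
class DataInstance:
    """One record of one schema entity.

    ``attribute_values`` maps *concrete* attribute paths to ordered literal
    values.  Folded value-group occurrences carry a positional index in the
    first step (``property[0]/@name``) so that predicate paths can correlate
    sibling values; plain attributes are stored unindexed (``@geneId``).
    """

    entity: str
    local_id: str
    attribute_values: dict[str, list[str]] = field(default_factory=dict)
    links: list[tuple[str, str]] = field(default_factory=list)
    source_id: str = ""

    def add_value(self, path: str, value: str) -> None:
        self.attribute_values.setdefault(path, []).append(value)


# ---------------------------------------------------------------------------
# Path expressions
# ---------------------------------------------------------------------------

_STEP_RE = re.compile(
    r"""^(?P<at>@)?(?P<name>[A-Za-z_][\w.\-]*)
        (?:\[@(?P<pattr>[A-Za-z_][\w.\-]*)\s*=\s*
        (?:"(?P<dlit>[^"]*)"|'(?P<slit>[^']*)')\])?$""",
    re.VERBOSE,
)

_IDX_RE = re.compile(r"^(?P<name>[^\[\]@]+)\[(?P<idx>\d+)\]$")


@dataclass(frozen=True)
class PathStep:
    name: str
    is_attr: bool
    pred_attr: Optional[str] = None
    pred_value: Optional[str] = None


def parse_path(path: str) -> list[PathStep]:
    """Parse a path expression; raise :class:`PathSyntaxError` if invalid."""
    if not path or not path.strip():
        raise PathSyntaxError("empty path expression")
    steps = []
    for raw in path.split("/"):
        m = _STEP_RE.match(raw.strip())
        if not m:
            raise PathSyntaxError(f"invalid path step {raw!r} in {path!r}")
        if m.group("at") and (m.group("pattr") is not None):
            raise PathSyntaxError(
                f"predicate not allowed on attribute step {raw!r}")
        lit = m.group("dlit") if m.group("dlit") is not None else m.group("slit")
        steps.append(PathStep(
            name=m.group("name"),
            is_attr=bool(m.group("at")),
            pred_attr=m.group("pattr"),
            pred_value=lit,
        ))
    if any(s.is_attr for s in steps[:-1]):
        raise PathSyntaxError(f"attribute step must be final in {path!r}")
    return steps


def _split_concrete(key: str) -> list[tuple[str, Optional[int], bool]]:
    """Split a stored concrete key into (name, occurrence-index, is_attr)."""
    out = []
    for raw in key.split("/"):
        is_attr = raw.startswith("@")
        if is_attr:
            raw = raw[1:]
        m = _IDX_RE.match(raw)
        if m:
            out.append((m.group("name"), int(m.group("idx")), is_attr))
        else:
            out.append((raw, None, is_attr))
    return out


def canonical_path(path: str) -> str:
    """The path with predicates and indices stripped (for schema lookup)."""
    steps = parse_path(path)
    return "/".join(("@" if s.is_attr else "") + s.name for s in steps)


def resolve_path(instance: DataInstance, path: str) -> list[str]:
    """Resolve a path expression on one instance.

    Returns all matching literal values in document/row order; an empty
    result is a valid outcome, never an error (absence is ``[]``).
    """
    steps = parse_path(path)
    values: list[str] = []
    for key, vals in instance.attribute_values.items():
        concrete = _split_concrete(key)
        if len(concrete) != len(steps):
            continue
        ok = True
        for (cname, cidx, cattr), step in zip(concrete, steps):
            if cname != step.name or cattr != step.is_attr:
                ok = False
                break
            if step.pred_attr is not None:
                # Sibling key sharing this step's occurrence index.
                sib = (f"{cname}[{cidx}]" if cidx is not None else cname)
                sib += f"/@{step.pred_attr}"
                if step.pred_value not in instance.attribute_values.get(sib, []):
                    ok = False
                    break
        if ok:
            values.extend(vals)
    return values


# ---------------------------------------------------------------------------
# XML Schema subset reader
# ---------------------------------------------------------------------------

_FORBIDDEN_XSD = ("import", "include", "redefine", "choice", "all", "group",
                  "attributeGroup", "union", "list")


def _xsd_kind(type_name: Optional[str]) -> Optional[str]:
    """Value kind for an XSD type reference; None if not a built-in simple."""
    if type_name is None:
        return None
    local = type_name.split(":")[-1]
    return _XSD_KIND.get(local)


class _XsdElement:
    """Resolved view of one element declaration in the subset."""

    def __init__(self, name, kind, attrs, children):
        self.name = name
        self.kind = kind              # value kind if simple, else None
        self.attrs = attrs            # list[(name, value_kind)]
        self.children = children      # list[_XsdElement]

    @property
    def is_complex(self) -> bool:
        return self.kind is None

    @property
    def is_value_group(self) -> bool:
        """Complex, has element children, and every child is simple."""
        return (self.is_complex and self.children
                and all(not c.is_complex for c in self.children))


def _parse_xsd(doc: str):
    try:
        root = etree.fromstring(doc.encode() if isinstance(doc, str) else doc)
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"malformed XML Schema: {exc}") from exc
    if etree.QName(root).localname != "schema":
        raise XmlParseError("document root is not an XML Schema")
    for el in root.iter():
        if not isinstance(el.tag, str):
            continue
        local = etree.QName(el).localname
        if local in _FORBIDDEN_XSD:
            raise UnsupportedConstructError(
                f"unsupported XML Schema construct xs:{local}")
        if el.get("substitutionGroup"):
            raise UnsupportedConstructError(
                "unsupported XML Schema construct substitutionGroup")
    return root


def _xsd_children(node, tag):
    return [c for c in node if isinstance(c.tag, str)
            and etree.QName(c).localname == tag]


def _resolve_element(el, named_types, seen) -> _XsdElement:
    name = el.get("name")
    if name is None:
        raise UnsupportedConstructError("element without a name (ref?)")
    type_ref = el.get("type")
    kind = _xsd_kind(type_ref)
    if kind is not None:
        return _XsdElement(name, kind, [], [])
    inline = _xsd_children(el, "complexType")
    if type_ref is not None:
        local = type_ref.split(":")[-1]
        if local not in named_types:
            raise DanglingReferenceError(f"unknown type {type_ref!r}")
        ct = named_types[local]
    elif inline:
        ct = inline[0]
    else:
        simple = _xsd_children(el, "simpleType")
        if simple:
            restr = _xsd_children(simple[0], "restriction")
            base = restr[0].get("base") if restr else None
            return _XsdElement(name, _xsd_kind(base) or "text", [], [])
        return _XsdElement(name, "text", [], [])
    if name in seen:
        raise UnsupportedConstructError(f"recursive element {name!r}")
    attrs = []
    for a in _xsd_children(ct, "attribute"):
        attrs.append((a.get("name"), _xsd_kind(a.get("type")) or "text"))
    children = []
    for seq in _xsd_children(ct, "sequence"):
        for sub in _xsd_children(seq, "element"):
            children.append(_resolve_element(sub, named_types, seen | {name}))
    return _XsdElement(name, None, attrs, children)


def load_xml_schema(xsd_document: str,
                    keys: Optional[dict[str, str]] = None) -> InputSchema:
    """Read an XML Schema (supported subset) into an :class:`InputSchema`.

    Complex-typed elements become entities; XML attributes and simple-typed
    child elements become attributes; nesting between complex elements
    becomes ``xml-containment`` relations.  Keyed value groups (see module
    docstring) fold into their parent entity's attribute paths.

    ``keys`` optionally names the identifying attribute path per entity
    (recorded as ``key_attribute``); the XSD subset itself carries no key
    declarations.
    """
    root = _parse_xsd(xsd_document)
    named_types = {ct.get("name"): ct
                   for ct in _xsd_children(root, "complexType")
                   if ct.get("name")}
    globals_ = _xsd_children(root, "element")
    if not globals_:
        raise UnsupportedConstructError("schema declares no global element")
    schema = InputSchema(name=root.get("id") or "xml-schema", kind="xml")
    keys = keys or {}

    def visit(xel: _XsdElement, parent: Optional[str]) -> None:
        if not xel.is_complex:
            return
        entity = SchemaEntity(name=xel.name,
                              key_attribute=keys.get(xel.name))
        for aname, akind in xel.attrs:
            entity.add_attribute(SchemaAttribute(xel.name, f"@{aname}", akind))
        nested = []
        for child in xel.children:
            if not child.is_complex:
                entity.add_attribute(
                    SchemaAttribute(xel.name, child.name, child.kind))
            elif child.is_value_group:
                for aname, akind in child.attrs:
                    entity.add_attribute(SchemaAttribute(
                        xel.name, f"{child.name}/@{aname}", akind))
                for grand in child.children:
                    entity.add_attribute(SchemaAttribute(
                        xel.name, f"{child.name}/{grand.name}", grand.kind))
            else:
                nested.append(child)
        schema.add_entity(entity)
        for child in nested:
            visit(child, xel.name)
            schema.add_relation(SchemaRelation(
                name=f"{xel.name}/{child.name}",
                source_entity=xel.name,
                target_entity=child.name,
                realization="xml-containment"))

    for gl in globals_:
        visit(_resolve_element(gl, named_types, set()), None)
    return schema


# ---------------------------------------------------------------------------
# Relational / tabular schema reader
# ---------------------------------------------------------------------------

_CREATE_RE = re.compile(
    r"create\s+table\s+(?P<name>\w+)\s*\((?P<body>.*?)\)\s*;",
    re.IGNORECASE | re.DOTALL)
_FK_RE = re.compile(
    r"foreign\s+key\s*\(\s*(?P<col>\w+)\s*\)\s*references\s+"
    r"(?P<table>\w+)\s*(?:\(\s*(?P<refcol>\w+)\s*\))?",
    re.IGNORECASE)
_PK_CLAUSE_RE = re.compile(
    r"primary\s+key\s*\(\s*(?P<cols>[\w\s,]+)\)", re.IGNORECASE)

_SQL_KIND = {
    "int": "integer", "integer": "integer", "bigint": "integer",
    "smallint": "integer", "serial": "integer",
    "decimal": "decimal", "numeric": "decimal", "real": "decimal",
    "float": "decimal", "double": "decimal",
    "boolean": "boolean", "bool": "boolean",
}


def _split_ddl_items(body: str) -> list[str]:
    items, depth, cur = [], 0, []
    for ch in body:
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
        if ch == "," and depth == 0:
            items.append("".join(cur).strip())
            cur = []
        else:
            cur.append(ch)
    tail = "".join(cur).strip()
    if tail:
        items.append(tail)
    return items


def _load_ddl(descriptor: str) -> InputSchema:
    schema = InputSchema(name="relational-schema", kind="relational")
    pending_fks = []
    for m in _CREATE_RE.finditer(descriptor):
        table = m.group("name")
        entity = SchemaEntity(name=table)
        pk_cols: list[str] = []
        for item in _split_ddl_items(m.group("body")):
            fk = _FK_RE.match(item)
            if fk:
                pending_fks.append((table, fk.group("col"), fk.group("table")))
                continue
            pkc = _PK_CLAUSE_RE.match(item)
            if pkc:
                pk_cols.extend(c.strip() for c in pkc.group("cols").split(","))
                continue
            parts = item.split()
            if len(parts) < 2:
                raise UnsupportedConstructError(f"cannot parse column {item!r}")
            col, sqltype = parts[0], parts[1].lower().split("(")[0]
            kind = _SQL_KIND.get(sqltype, "text")
            entity.add_attribute(SchemaAttribute(table, col, kind))
            rest = " ".join(parts[2:]).lower()
            if "primary key" in rest:
                pk_cols.append(col)
            refm = re.search(r"references\s+(\w+)", rest)
            if refm:
                pending_fks.append((table, col, refm.group(1)))
        if len(pk_cols) == 1:
            entity.key_attribute = pk_cols[0]
        elif len(pk_cols) > 1:
            schema.warnings.append(
                f"table {table!r} has a composite primary key; "
                "no key_attribute recorded")
        schema.add_entity(entity)
    for table, col, ref in pending_fks:
        if ref not in schema.entities:
            raise DanglingReferenceError(
                f"foreign key {table}.{col} references undeclared "
                f"table {ref!r}")
        schema.add_relation(SchemaRelation(
            name=f"{table}.{col}", source_entity=table, target_entity=ref,
            realization="foreign-key"))
    return schema


def _load_yaml_descriptor(descriptor: str) -> InputSchema:
    import yaml
    data = yaml.safe_load(descriptor)
    schema = InputSchema(name=str(data.get("name", "relational-schema")),
                         kind="relational")
    tables = data.get("tables", {})
    for table, spec in tables.items():
        entity = SchemaEntity(name=table)
        for col, kind in (spec.get("columns") or {}).items():
            if kind not in VALUE_KINDS:
                raise UnsupportedConstructError(
                    f"unknown value kind {kind!r} for {table}.{col}")
            entity.add_attribute(SchemaAttribute(table, col, kind))
        pk = spec.get("primary_key")
        if isinstance(pk, list):
            if len(pk) == 1:
                entity.key_attribute = pk[0]
            else:
                schema.warnings.append(
                    f"table {table!r} has a composite primary key; "
                    "no key_attribute recorded")
        elif pk:
            entity.key_attribute = pk
        schema.add_entity(entity)
    for table, spec in tables.items():
        for fk in (spec.get("foreign_keys") or []):
            ref = fk["references"]
            if ref not in schema.entities:
                raise DanglingReferenceError(
                    f"foreign key {table}.{fk['column']} references "
                    f"undeclared table {ref!r}")
            schema.add_relation(SchemaRelation(
                name=f"{table}.{fk['column']}",
                source_entity=table, target_entity=ref,
                realization="foreign-key"))
    return schema


def load_tabular_schema(descriptor: str) -> InputSchema:
    """Read DDL text (CREATE TABLE subset) or a YAML table descriptor.

    Tables become entities, columns attributes, foreign keys relations
    (``foreign-key`` realization, source = referencing table); a
    single-column primary key is recorded as the entity's key attribute.
    """
    if re.search(r"^\s*create\s+table", descriptor,
                 re.IGNORECASE | re.MULTILINE):
        return _load_ddl(descriptor)
    return _load_yaml_descriptor(descriptor)


# ---------------------------------------------------------------------------
# Instance readers
# ---------------------------------------------------------------------------

def read_xml_instances(xml_document: str, schema: InputSchema,
                       strict: bool = True,
                       source_id: str = "xml") -> Iterator[DataInstance]:
    """Yield one :class:`DataInstance` per entity-element occurrence.

    Instances appear in document order; containment links are recorded on
    the relation-source (parent) instance; the local id is the entity's key
    attribute value when declared, else an entity-prefixed ordinal.
    """
    try:
        root = etree.fromstring(
            xml_document.encode() if isinstance(xml_document, str)
            else xml_document)
    except etree.XMLSyntaxError as exc:
        raise XmlParseError(f"malformed XML document: {exc}") from exc

    counters: dict[str, int] = {}
    results: list[DataInstance] = []

    group_first_steps = {}
    for ent in schema.entities.values():
        group_first_steps[ent.name] = {
            p.split("/")[0] for p in ent.attributes if "/" in p}

    def handle(el, parent_inst: Optional[DataInstance],
               parent_entity: Optional[str]):
        tag = etree.QName(el).localname
        if tag not in schema.entities:
            msg = f"element {tag!r} not declared in schema"
            if strict:
                raise StrictReadError(msg)
            logger.warning("lenient read: skipping %s", msg)
            return
        entity = schema.entities[tag]
        counters[tag] = counters.get(tag, 0) + 1
        inst = DataInstance(entity=tag, local_id="", source_id=source_id)
        for aname, aval in el.attrib.items():
            inst.add_value(f"@{aname}", aval)
        group_counter: dict[str, int] = {}
        child_entities = []
        for child in el:
            if not isinstance(child.tag, str):
                continue
            ctag = etree.QName(child).localname
            if ctag in schema.entities:
                child_entities.append(child)
            elif ctag in group_first_steps[tag]:
                idx = group_counter.get(ctag, 0)
                group_counter[ctag] = idx + 1
                for ganame, gaval in child.attrib.items():
                    inst.add_value(f"{ctag}[{idx}]/@{ganame}", gaval)
                for gchild in child:
                    if isinstance(gchild.tag, str):
                        gname = etree.QName(gchild).localname
                        inst.add_value(f"{ctag}[{idx}]/{gname}",
                                       (gchild.text or "").strip())
            elif f"{ctag}" in entity.attributes:
                inst.add_value(ctag, (child.text or "").strip())
            else:
                msg = (f"element {ctag!r} under {tag!r} not declared "
                       "in schema")
                if strict:
                    raise StrictReadError(msg)
                logger.warning("lenient read: skipping %s", msg)
        if entity.key_attribute and resolve_path(inst, entity.key_attribute):
            inst.local_id = resolve_path(inst, entity.key_attribute)[0]
        else:
            inst.local_id = f"{tag}_{counters[tag]}"
        results.append(inst)
        if parent_inst is not None:
            rel_name = f"{parent_entity}/{tag}"
            if rel_name in schema.relations:
                parent_inst.links.append((rel_name, inst.local_id))
        for child in child_entities:
            handle(child, inst, tag)

    if isinstance(root.tag, str):
        tag = etree.QName(root).localname
        if tag in schema.entities:
            handle(root, None, None)
        else:
            # Wrapper root: treat each declared child as a document root.
            for child in root:
                if isinstance(child.tag, str):
                    handle(child, None, None)
    yield from results


def read_tabular_instances(rows, schema: InputSchema,
                           strict: bool = True,
                           source_id: str = "tabular"
                           ) -> Iterator[DataInstance]:
    """Yield one :class:`DataInstance` per row.

    ``rows`` maps table name to either a list of dict rows or CSV text
    (RFC 4180, UTF-8, header row).  Foreign-key columns produce links;
    empty cells produce absent values, never empty-text literals.
    """
    fk_by_table: dict[str, dict[str, SchemaRelation]] = {}
    for rel in schema.relations.values():
        if rel.realization == "foreign-key":
            col = rel.name.split(".", 1)[1]
            fk_by_table.setdefault(rel.source_entity, {})[col] = rel

    for table, data in rows.items():
        if table not in schema.entities:
            msg = f"table {table!r} not declared in schema"
            if strict:
                raise StrictReadError(msg)
            logger.warning("lenient read: skipping %s", msg)
            continue
        entity = schema.entities[table]
        if isinstance(data, str):
            reader = csv.DictReader(io.StringIO(data))
            dict_rows = list(reader)
            headers = reader.fieldnames or []
        else:
            dict_rows = list(data)
            headers = sorted({k for r in dict_rows for k in r})
        unknown = [h for h in headers if h not in entity.attributes]
        if unknown:
            msg = (f"columns {unknown} not declared for table {table!r}")
            if strict:
                raise StrictReadError(msg)
            logger.warning("lenient read: ignoring %s", msg)
        seen_keys: set[str] = set()
        for i, row in enumerate(dict_rows, start=1):
            inst = DataInstance(entity=table, local_id="",
                                source_id=source_id)
            for col, cell in row.items():
                if col not in entity.attributes or cell is None:
                    continue
                cell = str(cell)
                if cell == "":
                    continue   # absent value, not an empty literal
                kind = entity.attributes[col].value_kind
                try:
                    coerce_value(kind, cell)
                except CoercionError as exc:
                    raise CoercionError(
                        f"row {i} of table {table!r}, column {col!r}: "
                        f"{exc}") from exc
                inst.add_value(col, cell)
                fk = fk_by_table.get(table, {}).get(col)
                if fk is not None:
                    inst.links.append((fk.name, cell))
            if entity.key_attribute:
                kv = resolve_path(inst, entity.key_attribute)
                if kv:
                    if kv[0] in seen_keys:
                        msg = (f"duplicate primary key {kv[0]!r} in table "
                               f"{table!r} (row {i})")
                        if strict:
                            raise StrictReadError(msg)
                        logger.warning("lenient read: skipping %s", msg)
                        continue
                    seen_keys.add(kv[0])
                    inst.local_id = kv[0]
            if not inst.local_id:
                inst.local_id = f"{table}_{i}"
            yield inst
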