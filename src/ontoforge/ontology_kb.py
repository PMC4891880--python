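"""Target ontology, knowledge base of generated individuals, URIs, output.

The ontology (classes, datatype/object properties with declared domains and
ranges, disjointness, the subclass order) is read with ``rdflib`` from
RDF/XML or Turtle.  Generated individuals accumulate in a
:class:`KnowledgeBase` together with ``owl:sameAs`` / ``owl:differentFrom``
links.  Admissibility is enforced by a structural consistency check —
class disjointness (direct and inherited), datatype-range conformance,
object-property domain/range as asserted-type checks, and sameAs vs
differentFrom clashes — a decidable core standing in front of a pluggable
external DL-reasoner hook.

Serialization is canonical: triples are emitted fully sorted, so knowledge
bases that are equal as sets of assertions serialize byte-identically.
"""

from __future__ import annotations

import json
import re
import subprocess
import urllib.parse
from dataclasses import dataclass, field
from typing import Optional, Union

from rdflib import BNode, Graph, Literal, Namespace, URIRef
from rdflib.namespace import OWL, RDF, RDFS, XSD

from .errors import (
    OntoforgeError,
    SerializationRefusedError,
    UnknownTermError,
)

XSD_STRING = str(XSD.string)
XSD_INTEGER = str(XSD.integer)
XSD_DECIMAL = str(XSD.decimal)
XSD_BOOLEAN = str(XSD.boolean)

#: value kinds of the schema model mapped to XSD datatypes
KIND_TO_XSD = {
    "text": XSD_STRING,
    "integer": XSD_INTEGER,
    "decimal": XSD_DECIMAL,
    "boolean": XSD_BOOLEAN,
}

_LEXICAL = {
    XSD_INTEGER: re.compile(r"^[+-]?\d+$"),
    XSD_DECIMAL: re.compile(r"^[+-]?(\d+(\.\d*)?|\.\d+)$"),
    str(XSD.float): re.compile(r"^([+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?|INF|-INF|NaN)$"),
    str(XSD.double): re.compile(r"^([+-]?(\d+(\.\d*)?|\.\d+)([eE][+-]?\d+)?|INF|-INF|NaN)$"),
    XSD_BOOLEAN: re.compile(r"^(true|false|1|0)$"),
}


def local_name(uri: str) -> str:
    for sep in ("#", "/"):
        if sep in uri:
            tail = uri.rsplit(sep, 1)[1]
            if tail:
                return tail
    return uri


# ---------------------------------------------------------------------------
# Ontology terms and class expressions
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassRef:
    uri: str
    label: str = ""

    def __post_init__(self):
        if not self.uri.startswith("http"):
            raise ValueError(f"class URI must be absolute HTTP: {self.uri!r}")

    def render(self) -> str:
        return self.uri


@dataclass(frozen=True)
class PropertyRef:
    uri: str
    label: str = ""
    kind: str = "object"          # object | datatype
    domain: Optional[str] = None  # class URI
    range: Optional[str] = None   # class URI or datatype URI


@dataclass(frozen=True)
class Existential:
    """``property some Filler`` — the only supported restriction form."""
    property_uri: str
    filler_uri: str

    def render(self) -> str:
        return f"({self.property_uri} some {self.filler_uri})"


@dataclass(frozen=True)
class Intersection:
    operands: tuple   # of ClassRef / Existential / Intersection

    def render(self) -> str:
        return "(" + " and ".join(o.render() for o in self.operands) + ")"


ClassExpression = Union[ClassRef, Existential, Intersection]


def named_parts(expr: ClassExpression) -> set[str]:
    """Named-class URIs an individual provably belongs to via ``expr``."""
    if isinstance(expr, ClassRef):
        return {expr.uri}
    if isinstance(expr, Intersection):
        out: set[str] = set()
        for op in expr.operands:
            out |= named_parts(op)
        return out
    return set()   # an existential alone names no class of the subject


# ---------------------------------------------------------------------------
# Ontology model
# ---------------------------------------------------------------------------

@dataclass
class OntologyModel:
    classes: dict[str, ClassRef] = field(default_factory=dict)
    datatype_properties: dict[str, PropertyRef] = field(default_factory=dict)
    object_properties: dict[str, PropertyRef] = field(default_factory=dict)
    disjointness: set[frozenset] = field(default_factory=set)
    subclass: dict[str, set[str]] = field(default_factory=dict)  # child->parents
    prefixes: dict[str, str] = field(default_factory=dict)
    capability_report: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def property(self, uri: str) -> Optional[PropertyRef]:
        return self.datatype_properties.get(uri) or \
            self.object_properties.get(uri)

    def ancestors(self, class_uri: str) -> set[str]:
        """Reflexive-transitive superclass closure."""
        out = {class_uri}
        frontier = [class_uri]
        while frontier:
            cur = frontier.pop()
            for parent in self.subclass.get(cur, ()):
                if parent not in out:
                    out.add(parent)
                    frontier.append(parent)
        return out

    def expand_prefixed(self, name: str) -> str:
        """Resolve ``prefix:Local`` against the declared prefixes."""
        if name.startswith("http://") or name.startswith("https://"):
            return name
        if ":" in name:
            prefix, local = name.split(":", 1)
            if prefix in self.prefixes:
                return self.prefixes[prefix] + local
            raise UnknownTermError(f"unknown prefix {prefix!r} in {name!r}")
        # bare local name: unique match among declared terms
        cands = [u for u in list(self.classes) +
                 list(self.datatype_properties) + list(self.object_properties)
                 if local_name(u) == name]
        if len(cands) == 1:
            return cands[0]
        raise UnknownTermError(
            f"cannot resolve name {name!r} ({len(cands)} candidates)")

    def check_invariants(self) -> None:
        # subclass acyclicity
        for cls in self.subclass:
            seen, stack = set(), [cls]
            while stack:
                cur = stack.pop()
                for parent in self.subclass.get(cur, ()):
                    if parent == cls:
                        raise OntoforgeError(
                            f"subclass cycle through {cls!r}")
                    if parent not in seen:
                        seen.add(parent)
                        stack.append(parent)


_CAPTURED_PREDICATES = {
    RDF.type, RDFS.subClassOf, RDFS.domain, RDFS.range, RDFS.label,
    OWL.disjointWith, RDFS.comment,
}


def load_ontology(document: str, format: str = "turtle") -> OntologyModel:
    """Parse an OWL ontology document into an :class:`OntologyModel`.

    Unsupported axiom kinds are recorded in ``capability_report``, never
    dropped silently; properties without a declared domain or range get a
    warning (checks that would need them are skipped).
    """
    fmt = {"rdfxml": "xml", "turtle": "turtle"}.get(format)
    if fmt is None:
        raise OntoforgeError(f"unknown ontology format {format!r}")
    graph = Graph()
    try:
        graph.parse(data=document, format=fmt)
    except Exception as exc:
        raise OntoforgeError(f"ontology parse failure ({format}): {exc}") \
            from exc
    model = OntologyModel()
    declared_prefixes = {prefix: str(ns) for prefix, ns
                         in graph.namespaces() if prefix}

    def label_of(node) -> str:
        val = graph.value(node, RDFS.label)
        return str(val) if val is not None else ""

    for cls in sorted(set(graph.subjects(RDF.type, OWL.Class)) |
                      set(graph.subjects(RDF.type, RDFS.Class)),
                      key=str):
        if isinstance(cls, URIRef):
            model.classes[str(cls)] = ClassRef(str(cls), label_of(cls))
        else:
            model.capability_report.append(
                "anonymous class declaration not captured")
    for kind, target in (("datatype", OWL.DatatypeProperty),
                         ("object", OWL.ObjectProperty)):
        for prop in sorted(graph.subjects(RDF.type, target), key=str):
            if not isinstance(prop, URIRef):
                continue
            dom = graph.value(prop, RDFS.domain)
            rng = graph.value(prop, RDFS.range)
            if dom is None or rng is None:
                model.warnings.append(
                    f"property {prop} lacks declared domain/range; "
                    "related checks are skipped")
            ref = PropertyRef(
                uri=str(prop), label=label_of(prop), kind=kind,
                domain=str(dom) if isinstance(dom, URIRef) else None,
                range=str(rng) if isinstance(rng, URIRef) else None)
            if kind == "datatype":
                model.datatype_properties[str(prop)] = ref
            else:
                model.object_properties[str(prop)] = ref
    for a, b in graph.subject_objects(OWL.disjointWith):
        if isinstance(a, URIRef) and isinstance(b, URIRef):
            model.disjointness.add(frozenset((str(a), str(b))))
    for child, parent in graph.subject_objects(RDFS.subClassOf):
        if isinstance(child, URIRef) and isinstance(parent, URIRef):
            model.subclass.setdefault(str(child), set()).add(str(parent))
    for s, p, o in graph:
        if p not in _CAPTURED_PREDICATES and isinstance(s, URIRef):
            model.capability_report.append(
                f"axiom kind {p} not captured ({s})")
    if len(graph) == 0:
        model.warnings.append("ontology document is empty")
    # keep only prefixes that back a declared term (rdflib binds a large
    # set of well-known namespaces by default which would bloat output)
    term_uris = (set(model.classes) | set(model.datatype_properties) |
                 set(model.object_properties))
    for prefix, ns in sorted(declared_prefixes.items()):
        if any(uri.startswith(ns) for uri in term_uris):
            model.prefixes[prefix] = ns
    model.check_invariants()
    return model


# ---------------------------------------------------------------------------
# URI policy
# ---------------------------------------------------------------------------

@dataclass
class URIPolicy:
    default_base: str = "http://example.org/data/"
    per_class_base: dict[str, str] = field(default_factory=dict)
    mode: dict[str, str] = field(default_factory=dict)  # class uri -> mode

    def __post_init__(self):
        for base in [self.default_base, *self.per_class_base.values()]:
            if not base.startswith("http") or base[-1] not in "/#":
                raise ValueError(
                    f"URI base must be absolute HTTP ending in / or #: "
                    f"{base!r}")


def mint_uri(policy: URIPolicy, class_ref: ClassRef, token: str) -> str:
    """Deterministically mint the URI for one individual.

    ``mint-local`` (default): base + class local name + "/" + encoded token.
    ``adopt-external``: base + encoded token — the external resource's own
    URI scheme (e.g. UniProt accessions) is adopted verbatim.
    """
    if not token:
        raise OntoforgeError("cannot mint a URI from an empty token")
    base = policy.per_class_base.get(class_ref.uri, policy.default_base)
    mode = policy.mode.get(class_ref.uri, "mint-local")
    enc = urllib.parse.quote(token, safe="")
    if mode == "adopt-external":
        return base + enc
    return f"{base}{local_name(class_ref.uri)}/{enc}"


# ---------------------------------------------------------------------------
# Individuals, batches, knowledge base
# ---------------------------------------------------------------------------

@dataclass
class Individual:
    uri: str
    asserted_classes: list = field(default_factory=list)   # ClassExpression
    data_assertions: list = field(default_factory=list)    # (prop,lex,dtype)
    object_assertions: list = field(default_factory=list)  # (prop, obj uri)
    provenance: list = field(default_factory=list)         # (src,entity,lid)
    token: str = ""    # the minted-URI token; the individual's RENDERING

    def add_class(self, expr: ClassExpression) -> None:
        if expr not in self.asserted_classes:
            self.asserted_classes.append(expr)

    def add_data(self, prop: str, lexical: str, datatype: str) -> None:
        t = (prop, lexical, datatype)
        if t not in self.data_assertions:
            self.data_assertions.append(t)

    def add_object(self, prop: str, obj_uri: str) -> None:
        t = (prop, obj_uri)
        if t not in self.object_assertions:
            self.object_assertions.append(t)

    def add_provenance(self, source_id: str, entity: str, lid: str) -> None:
        t = (source_id, entity, lid)
        if t not in self.provenance:
            self.provenance.append(t)

    def named_classes(self) -> set[str]:
        out: set[str] = set()
        for expr in self.asserted_classes:
            out |= named_parts(expr)
        return out

    def signature(self):
        """Order-free content signature (used for KB equality)."""
        return (self.uri,
                frozenset(e.render() for e in self.asserted_classes),
                frozenset(self.data_assertions),
                frozenset(self.object_assertions))


@dataclass
class AxiomBatch:
    """One unit of content presented to the knowledge base for admission."""
    new_individuals: list = field(default_factory=list)   # [Individual]
    assertions: list = field(default_factory=list)
    # assertion forms:
    #   ("class",  subject_uri, ClassExpression)
    #   ("data",   subject_uri, prop_uri, lexical, datatype_uri)
    #   ("object", subject_uri, prop_uri, object_uri)

    def subjects(self) -> set[str]:
        return ({i.uri for i in self.new_individuals} |
                {a[1] for a in self.assertions})


@dataclass
class Violation:
    kind: str
    message: str
    assertions: list = field(default_factory=list)

    def to_dict(self):
        return {"kind": self.kind, "message": self.message,
                "assertions": [list(a) for a in self.assertions]}


@dataclass
class ViolationReport:
    violations: list = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.violations

    def add(self, kind: str, message: str, assertions=()) -> None:
        self.violations.append(Violation(kind, message, list(assertions)))

    def to_json(self) -> str:
        return json.dumps([v.to_dict() for v in self.violations], indent=2)


@dataclass
class KnowledgeBase:
    ontology: OntologyModel
    individuals: dict[str, Individual] = field(default_factory=dict)
    same_as: list[frozenset] = field(default_factory=list)
    different_from: list[frozenset] = field(default_factory=list)
    external_uris: set[str] = field(default_factory=set)

    # -- sameAs closure ----------------------------------------------------
    def representative(self, uri: str) -> str:
        """Canonical representative of a sameAs component (lexicographic
        minimum, so the choice is stable under insertion order)."""
        comp = self._component(uri)
        return min(comp) if comp else uri

    def _component(self, uri: str) -> set[str]:
        adj: dict[str, set[str]] = {}
        for pair in self.same_as:
            a, b = tuple(pair) if len(pair) == 2 else (next(iter(pair)),) * 2
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)
        if uri not in adj:
            return {uri}
        seen, stack = {uri}, [uri]
        while stack:
            cur = stack.pop()
            for nxt in adj.get(cur, ()):
                if nxt not in seen:
                    seen.add(nxt)
                    stack.append(nxt)
        return seen

    def known_uri(self, uri: str) -> bool:
        return uri in self.individuals or uri in self.external_uris

    def signature(self):
        return (frozenset(i.signature() for i in self.individuals.values()),
                frozenset(self.same_as),
                frozenset(self.different_from))


# ---------------------------------------------------------------------------
# Axiom admission
# ---------------------------------------------------------------------------

def _check_term(kb: KnowledgeBase, batch: AxiomBatch,
                prop: Optional[str] = None,
                cls: Optional[ClassExpression] = None,
                obj: Optional[str] = None) -> None:
    onto = kb.ontology
    if prop is not None and onto.property(prop) is None:
        raise UnknownTermError(f"undeclared property {prop!r}")
    if cls is not None:
        for uri in named_parts(cls):
            if uri not in onto.classes:
                raise UnknownTermError(f"undeclared class {uri!r}")
        if isinstance(cls, (Existential, Intersection)):
            for part in _expr_terms(cls):
                kind, uri = part
                if kind == "p" and onto.property(uri) is None:
                    raise UnknownTermError(f"undeclared property {uri!r}")
                if kind == "c" and uri not in onto.classes:
                    raise UnknownTermError(f"undeclared class {uri!r}")
    if obj is not None:
        # forward references to candidates admitted later in the run are
        # legitimate (the engine repairs rejected targets afterwards), so
        # only reject URIs that cannot name an individual at all
        if not obj.startswith("http"):
            raise UnknownTermError(
                f"object {obj!r} is not an absolute HTTP URI")


def _expr_terms(expr: ClassExpression):
    if isinstance(expr, ClassRef):
        yield ("c", expr.uri)
    elif isinstance(expr, Existential):
        yield ("p", expr.property_uri)
        yield ("c", expr.filler_uri)
    else:
        for op in expr.operands:
            yield from _expr_terms(op)


def assert_axioms(kb: KnowledgeBase, batch: AxiomBatch) -> KnowledgeBase:
    """Admit a batch into the KB.  Idempotent: re-asserting changes nothing.

    Individuals arriving under a URI that already names a KB individual are
    folded into it — individuals with the same URI are the same one.
    """
    for ind in batch.new_individuals:
        for expr in ind.asserted_classes:
            _check_term(kb, batch, cls=expr)
        for prop, _, _ in ind.data_assertions:
            _check_term(kb, batch, prop=prop)
        for prop, obj in ind.object_assertions:
            _check_term(kb, batch, prop=prop, obj=obj)
    for a in batch.assertions:
        if a[0] == "class":
            _check_term(kb, batch, cls=a[2])
        elif a[0] == "data":
            _check_term(kb, batch, prop=a[2])
        elif a[0] == "object":
            _check_term(kb, batch, prop=a[2], obj=a[3])
        subject = a[1]
        if subject not in kb.individuals and \
                subject not in {i.uri for i in batch.new_individuals}:
            raise UnknownTermError(f"assertion on unknown subject {subject!r}")

    for ind in batch.new_individuals:
        existing = kb.individuals.get(ind.uri)
        if existing is None:
            kb.individuals[ind.uri] = Individual(
                uri=ind.uri, token=ind.token,
                asserted_classes=list(ind.asserted_classes),
                data_assertions=list(ind.data_assertions),
                object_assertions=list(ind.object_assertions),
                provenance=list(ind.provenance))
        else:
            for expr in ind.asserted_classes:
                existing.add_class(expr)
            for t in ind.data_assertions:
                existing.add_data(*t)
            for t in ind.object_assertions:
                existing.add_object(*t)
            for t in ind.provenance:
                existing.add_provenance(*t)
    for a in batch.assertions:
        target = kb.individuals[a[1]]
        if a[0] == "class":
            target.add_class(a[2])
        elif a[0] == "data":
            target.add_data(a[2], a[3], a[4])
        else:
            target.add_object(a[2], a[3])
    return kb


# ---------------------------------------------------------------------------
# Consistency checking
# ---------------------------------------------------------------------------

def _combined_view(kb: KnowledgeBase, candidate: Optional[AxiomBatch]):
    """(uri -> (named classes, data, object)) over KB ∪ candidate."""
    view: dict[str, tuple[set, list, list]] = {}
    for uri, ind in kb.individuals.items():
        view[uri] = (set(ind.named_classes()),
                     list(ind.data_assertions),
                     list(ind.object_assertions))
    if candidate is not None:
        for ind in candidate.new_individuals:
            named, data, objs = view.setdefault(ind.uri, (set(), [], []))
            named |= ind.named_classes()
            data.extend(ind.data_assertions)
            objs.extend(ind.object_assertions)
        for a in candidate.assertions:
            named, data, objs = view.setdefault(a[1], (set(), [], []))
            if a[0] == "class":
                named |= named_parts(a[2])
            elif a[0] == "data":
                data.append((a[2], a[3], a[4]))
            else:
                objs.append((a[2], a[3]))
    return view


def check_consistency(kb: KnowledgeBase,
                      candidate: Optional[AxiomBatch] = None
                      ) -> ViolationReport:
    """Structural admissibility of KB ∪ candidate, without mutating the KB.

    Violation kinds: ``disjointness``, ``datatype-range``, ``object-range``,
    ``object-domain``, ``sameas-vs-differentfrom``.  An empty report means
    the content is admissible under the structural check set.
    """
    onto = kb.ontology
    report = ViolationReport()
    view = _combined_view(kb, candidate)

    closure_cache: dict[str, set[str]] = {}

    def closure(classes: set[str]) -> set[str]:
        out: set[str] = set()
        for c in classes:
            if c not in closure_cache:
                closure_cache[c] = onto.ancestors(c)
            out |= closure_cache[c]
        return out

    for uri in sorted(view):
        named, data, objs = view[uri]
        anc = closure(named)
        for pair in sorted(onto.disjointness, key=sorted):
            a, b = sorted(pair)
            if a in anc and b in anc:
                report.add(
                    "disjointness",
                    f"individual {uri} falls under disjoint classes "
                    f"{a} and {b}",
                    [("class", uri, a), ("class", uri, b)])
        for prop, lexical, dtype in sorted(data):
            decl = onto.datatype_properties.get(prop)
            rng = decl.range if decl else None
            check_dt = rng or dtype
            pat = _LEXICAL.get(check_dt)
            if pat is not None and not pat.match(lexical):
                report.add(
                    "datatype-range",
                    f"value {lexical!r} on {prop} is not a valid "
                    f"{local_name(check_dt)}",
                    [("data", uri, prop, lexical, dtype)])
        for prop, obj in sorted(objs):
            decl = onto.object_properties.get(prop)
            if decl is None:
                continue
            if decl.domain and named and decl.domain not in anc:
                report.add(
                    "object-domain",
                    f"subject {uri} of {prop} is not asserted under the "
                    f"declared domain {decl.domain}",
                    [("object", uri, prop, obj)])
            if decl.range and obj in view:
                obj_named = view[obj][0]
                if obj_named and decl.range not in closure(obj_named):
                    report.add(
                        "object-range",
                        f"object {obj} of {prop} is not asserted under "
                        f"the declared range {decl.range}",
                        [("object", uri, prop, obj)])

    for pair in sorted(kb.different_from, key=sorted):
        a, b = sorted(pair) if len(pair) == 2 else (list(pair)[0],) * 2
        if kb.representative(a) == kb.representative(b):
            report.add(
                "sameas-vs-differentfrom",
                f"{a} and {b} are both sameAs-connected and declared "
                "differentFrom",
                [("differentFrom", a, b)])
    return report


def invoke_reasoner_hook(kb: KnowledgeBase, command: list[str]) -> bool:
    """Shell out to an external DL reasoner on the serialized KB.

    The command receives the path of a Turtle file as its final argument
    and must print ``consistent yes`` or ``consistent no``.
    """
    import tempfile

    with tempfile.NamedTemporaryFile("w", suffix=".ttl", delete=False) as fh:
        fh.write(serialize_kb(kb, "turtle", "owl", override=True))
        path = fh.name
    out = subprocess.run(command + [path], capture_output=True, text=True,
                         check=True).stdout.lower()
    if "consistent yes" in out:
        return True
    if "consistent no" in out:
        return False
    raise OntoforgeError(f"reasoner output not understood: {out!r}")


# ---------------------------------------------------------------------------
# Serialization
# ---------------------------------------------------------------------------

def _esc(lit: str) -> str:
    return lit.replace("\\", "\\\\").replace('"', '\\"') \
              .replace("\n", "\\n").replace("\r", "\\r")


def _lit_ttl(lexical: str, datatype: str) -> str:
    if datatype == XSD_STRING or not datatype:
        return f'"{_esc(lexical)}"'
    return f'"{_esc(lexical)}"^^<{datatype}>'


def _expr_ttl(expr: ClassExpression) -> str:
    if isinstance(expr, ClassRef):
        return f"<{expr.uri}>"
    if isinstance(expr, Existential):
        return (f"[ a <{OWL.Restriction}> ; <{OWL.onProperty}> "
                f"<{expr.property_uri}> ; <{OWL.someValuesFrom}> "
                f"<{expr.filler_uri}> ]")
    inner = " ".join(_expr_ttl(o) for o in expr.operands)
    return f"[ a <{OWL.Class}> ; <{OWL.intersectionOf}> ( {inner} ) ]"


def kb_triples(kb: KnowledgeBase, profile: str = "rdf",
               emit_different_from: bool = False) -> list[tuple]:
    """All instance-level triples of the KB, in abstract form.

    Anonymous class expressions appear only in profile ``owl``; they are
    returned as ("expr", subject, expression) entries.
    """
    triples: list[tuple] = []
    for uri in kb.individuals:
        ind = kb.individuals[uri]
        for expr in ind.asserted_classes:
            if isinstance(expr, ClassRef):
                triples.append(("uri", uri, str(RDF.type), expr.uri))
            elif profile == "owl":
                triples.append(("expr", uri, expr))
        for prop, lexical, dtype in ind.data_assertions:
            triples.append(("lit", uri, prop, lexical, dtype))
        for prop, obj in ind.object_assertions:
            triples.append(("uri", uri, prop, obj))
    for pair in kb.same_as:
        a, b = sorted(pair) if len(pair) == 2 else (list(pair)[0],) * 2
        triples.append(("uri", a, str(OWL.sameAs), b))
    if emit_different_from and profile == "owl":
        for pair in kb.different_from:
            a, b = sorted(pair) if len(pair) == 2 else (list(pair)[0],) * 2
            triples.append(("uri", a, str(OWL.differentFrom), b))
    return triples


def serialize_kb(kb: KnowledgeBase, format: str = "turtle",
                 profile: str = "rdf", override: bool = False,
                 emit_different_from: bool = False) -> str:
    """Serialize the KB canonically (sorted subjects/predicates/objects).

    Refuses when the structural check reports violations, unless
    ``override`` is set.
    """
    if format not in ("turtle", "rdfxml"):
        raise OntoforgeError(f"unknown serialization format {format!r}")
    if profile not in ("rdf", "owl"):
        raise OntoforgeError(f"unknown output profile {profile!r}")
    if not override:
        report = check_consistency(kb)
        if not report.empty:
            raise SerializationRefusedError(
                f"knowledge base has {len(report.violations)} violation(s); "
                "pass override to serialize anyway")
    triples = kb_triples(kb, profile, emit_different_from)
    lines = []
    for t in triples:
        if t[0] == "uri":
            lines.append(f"<{t[1]}> <{t[2]}> <{t[3]}> .")
        elif t[0] == "lit":
            lines.append(f"<{t[1]}> <{t[2]}> {_lit_ttl(t[3], t[4])} .")
        else:
            lines.append(f"<{t[1]}> <{str(RDF.type)}> {_expr_ttl(t[2])} .")
    lines = sorted(set(lines))
    header = [f"@prefix {p}: <{ns}> ."
              for p, ns in sorted(kb.ontology.prefixes.items())]
    for p, ns in (("owl", str(OWL)), ("rdf", str(RDF)),
                  ("rdfs", str(RDFS)), ("xsd", str(XSD))):
        if p not in kb.ontology.prefixes:
            header.append(f"@prefix {p}: <{ns}> .")
    header = sorted(header)
    doc = "\n".join(header + [""] + lines) + "\n"
    if format == "turtle":
        return doc
    graph = Graph()
    graph.parse(data=doc, format="turtle")
    for p, ns in sorted(kb.ontology.prefixes.items()):
        graph.bind(p, Namespace(ns), replace=True)
    return graph.serialize(format="xml")


def parse_kb(document: str, ontology: OntologyModel,
             format: str = "turtle") -> KnowledgeBase:
    """Reload a serialized dataset into a :class:`KnowledgeBase`.

    Reconstructs individuals, sameAs/differentFrom links and the supported
    anonymous class expressions; provenance is not carried by the exchange
    formats and is re-seeded from the loading source.
    """
    fmt = {"rdfxml": "xml", "turtle": "turtle"}[format]
    graph = Graph()
    graph.parse(data=document, format=fmt)
    kb = KnowledgeBase(ontology=ontology)

    def ensure(uri: str) -> Individual:
        if uri not in kb.individuals:
            kb.individuals[uri] = Individual(
                uri=uri, token=local_name(uri),
                provenance=[("loaded", "", uri)])
        return kb.individuals[uri]

    def parse_expr(node) -> Optional[ClassExpression]:
        if isinstance(node, URIRef):
            return ClassRef(str(node))
        inter = graph.value(node, OWL.intersectionOf)
        if inter is not None:
            ops = []
            for item in graph.items(inter):
                sub = parse_expr(item)
                if sub is None:
                    return None
                ops.append(sub)
            return Intersection(tuple(ops))
        prop = graph.value(node, OWL.onProperty)
        filler = graph.value(node, OWL.someValuesFrom)
        if prop is not None and filler is not None:
            return Existential(str(prop), str(filler))
        return None

    for s, p, o in sorted(graph, key=lambda t: (str(t[0]), str(t[1]),
                                                str(t[2]))):
        if isinstance(s, BNode):
            continue
        su = str(s)
        if p == RDF.type:
            expr = parse_expr(o)
            if expr is not None:
                ensure(su).add_class(expr)
            continue
        if p == OWL.sameAs:
            pair = frozenset((su, str(o)))
            if pair not in kb.same_as:
                kb.same_as.append(pair)
            for u in (su, str(o)):
                if u not in kb.individuals:
                    kb.external_uris.add(u)
            continue
        if p == OWL.differentFrom:
            pair = frozenset((su, str(o)))
            if pair not in kb.different_from:
                kb.different_from.append(pair)
            continue
        pu = str(p)
        if isinstance(o, Literal):
            dtype = str(o.datatype) if o.datatype else XSD_STRING
            ensure(su).add_data(pu, str(o), dtype)
        elif isinstance(o, URIRef):
            ensure(su).add_object(pu, str(o))
    # objects referenced but never subjects are external or plain targets
    for ind in list(kb.individuals.values()):
        for _, obj in ind.object_assertions:
            if obj not in kb.individuals:
                kb.external_uris.add(obj)
    return kb
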