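"""Ontology transformation patterns: parse and instantiate axiom templates.

A pattern is the tuple <S, V>: a set of template statements over ontology
terms (S) and a set of variables (V).  The supported source grammar is the
subset of OPPL2 the published pattern examples span::

    ?chiralMolecule: INDIVIDUAL
    BEGIN
    ADD ?chiralMolecule instanceOf (Molecule and has_chemical_property some Chirality)
    END;

Variables are ``INDIVIDUAL`` or ``CONSTANT``; an INDIVIDUAL variable may
carry a generator ``create(?base.RENDERING+_SUFFIX)`` whose URI token is
the rendering (minted-URI token) of the base individual plus the suffix.
Statements are ``instanceOf`` (class expressions limited to intersections
and ``property some Class`` restrictions), object-property additions and
datatype-property additions.  Anything beyond this subset (SELECT, REMOVE,
OPPL queries) is rejected with an unsupported-construct error.

Instantiation binds variables to schema entities / attribute paths and
emits an :class:`~ontoforge.ontology_kb.AxiomBatch`.  Statements with no
source-bound variable are emitted on every instantiation: this fixed
content is the semantic-enrichment mechanism.  ``P some C`` restrictions
on an individual are made ground by minting one deterministic filler
individual of class ``C`` per subject, while the anonymous expression
membership itself is kept for the OWL output profile.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Optional

from .errors import (
    ClassificationError,
    PatternSyntaxError,
    UnsupportedConstructError,
)
from .ontology_kb import (
    AxiomBatch,
    ClassRef,
    Existential,
    Individual,
    Intersection,
    OntologyModel,
    URIPolicy,
    XSD_STRING,
    local_name,
    mint_uri,
)
from .schema_model import DataInstance, resolve_path

logger = logging.getLogger("ontoforge")

_FORBIDDEN_KEYWORDS = ("SELECT", "REMOVE", "WHERE", "MATCH", "CREATE ")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CreateExpression:
    base_variable: str   # e.g. "?protein"
    suffix: str          # e.g. "_CDS"


@dataclass(frozen=True)
class PatternVariable:
    name: str            # begins with "?"
    kind: str            # INDIVIDUAL | CONSTANT
    generator: Optional[CreateExpression] = None

    def __post_init__(self):
        if not self.name.startswith("?"):
            raise PatternSyntaxError(
                f"variable name must begin with '?': {self.name!r}")
        if self.generator is not None and self.kind != "INDIVIDUAL":
            raise PatternSyntaxError(
                f"generator only allowed on INDIVIDUAL variables "
                f"({self.name})")


@dataclass(frozen=True)
class PatternStatement:
    """One ADD statement.

    ``form`` is one of ``instanceOf`` / ``object`` / ``data``; ``subject``
    is a variable name; ``payload`` is the class-expression AST for
    instanceOf, ``(property, variable)`` for object, and
    ``(property, variable-or-("lit", text))`` for data.
    """
    form: str
    subject: str
    payload: tuple


@dataclass
class Pattern:
    name: str
    variables: dict[str, PatternVariable] = field(default_factory=dict)
    statements: list[PatternStatement] = field(default_factory=list)

    def check_invariants(self) -> None:
        if not self.statements:
            raise PatternSyntaxError(
                f"pattern {self.name!r} declares no statement")
        for st in self.statements:
            for var in statement_variables(st):
                if var not in self.variables:
                    raise PatternSyntaxError(
                        f"undeclared variable {var!r} in pattern "
                        f"{self.name!r}")
        for var in self.variables.values():
            if var.generator is not None:
                base = self.variables.get(var.generator.base_variable)
                if base is None or base.kind != "INDIVIDUAL":
                    raise PatternSyntaxError(
                        f"create() base {var.generator.base_variable!r} is "
                        f"not an INDIVIDUAL variable of pattern "
                        f"{self.name!r}")


@dataclass(frozen=True)
class BindingTarget:
    entity: Optional[str] = None
    path: Optional[str] = None


@dataclass
class PatternBinding:
    pattern: str
    bind: dict[str, BindingTarget] = field(default_factory=dict)
    anchor: Optional[str] = None   # entity name; defaulted when omitted

    def anchor_entity(self) -> str:
        if self.anchor:
            return self.anchor
        for target in self.bind.values():
            if target.entity and not target.path:
                return target.entity
        for target in self.bind.values():
            if target.entity:
                return target.entity
        raise ClassificationError(
            f"binding for pattern {self.pattern!r} has no anchor entity")


def statement_variables(st: PatternStatement) -> list[str]:
    out = [st.subject]
    if st.form == "object":
        out.append(st.payload[1])
    elif st.form == "data" and isinstance(st.payload[1], str):
        out.append(st.payload[1])
    return out


# ---------------------------------------------------------------------------
# Parsing
# ---------------------------------------------------------------------------

_DECL_RE = re.compile(
    r"^\?(?P<name>\w+)\s*:\s*(?P<kind>INDIVIDUAL|CONSTANT)\s*"
    r"(?:=\s*(?P<gen>create\(.*\))\s*)?$")
_CREATE_RE = re.compile(
    r"^create\(\s*\?(?P<base>\w+)\.RENDERING\s*\+\s*(?P<suffix>[^\s)]+)\s*\)$")
_ADD_RE = re.compile(r"^ADD\s+(?P<body>.+)$", re.IGNORECASE)


def _tokenize_expr(text: str) -> list[str]:
    return [t for t in re.findall(r"\(|\)|[^\s()]+", text)]


def _parse_class_expr(tokens: list[str], pos: int = 0):
    """Recursive-descent parse of ``name | prop some name | e and e | (e)``.

    Returns an AST of ("name", n) / ("some", p, c) / ("and", [asts]).
    """

    def parse_term(i):
        if i >= len(tokens):
            raise PatternSyntaxError("unexpected end of class expression")
        if tokens[i] == "(":
            ast, i = parse_expr(i + 1)
            if i >= len(tokens) or tokens[i] != ")":
                raise PatternSyntaxError("unbalanced parentheses")
            return ast, i + 1
        name = tokens[i]
        if i + 2 < len(tokens) and tokens[i + 1] == "some":
            filler = tokens[i + 2]
            return ("some", name, filler), i + 3
        if i + 1 < len(tokens) and tokens[i + 1] == "some":
            raise PatternSyntaxError("'some' without a filler")
        return ("name", name), i + 1

    def parse_expr(i):
        ast, i = parse_term(i)
        operands = [ast]
        while i < len(tokens) and tokens[i] == "and":
            nxt, i = parse_term(i + 1)
            operands.append(nxt)
        if len(operands) == 1:
            return operands[0], i
        return ("and", operands), i

    ast, end = parse_expr(pos)
    if end != len(tokens):
        raise PatternSyntaxError(
            f"trailing tokens in class expression: {tokens[end:]}")
    return ast


def _parse_statement(body: str) -> PatternStatement:
    parts = body.split(None, 2)
    if len(parts) < 3 or not parts[0].startswith("?"):
        raise PatternSyntaxError(f"cannot parse statement {body!r}")
    subject, keyword, rest = parts
    if keyword == "instanceOf":
        ast = _parse_class_expr(_tokenize_expr(rest))
        return PatternStatement("instanceOf", subject, (ast,))
    # property addition: object when the operand is a variable or data when
    # it is a quoted literal; CONSTANT variables are resolved to data later.
    prop = keyword
    operand = rest.strip().rstrip(",")
    if operand.startswith("?"):
        return PatternStatement("object", subject, (prop, operand))
    m = re.match(r'^"(?P<lit>.*)"$', operand)
    if m:
        return PatternStatement("data", subject, (prop, ("lit",
                                                         m.group("lit"))))
    raise PatternSyntaxError(
        f"statement operand must be a variable or quoted literal: "
        f"{operand!r}")


def parse_pattern(text: str, name: str = "pattern") -> Pattern:
    """Parse pattern source in the supported subset grammar."""
    for kw in _FORBIDDEN_KEYWORDS:
        if re.search(rf"\b{kw.strip()}\b", text) and kw != "CREATE ":
            raise UnsupportedConstructError(
                f"unsupported pattern construct {kw.strip()!r}")
    pattern = Pattern(name=name)
    in_body = False
    saw_end = False
    for raw in re.split(r"[\n,]", text):
        line = raw.strip().rstrip(",").strip()
        if not line:
            continue
        upper = line.upper()
        if upper == "BEGIN":
            in_body = True
            continue
        if upper in ("END;", "END"):
            saw_end = True
            in_body = False
            continue
        if not in_body:
            m = _DECL_RE.match(line)
            if not m:
                raise PatternSyntaxError(
                    f"cannot parse variable declaration {line!r}")
            gen = None
            if m.group("gen"):
                gm = _CREATE_RE.match(m.group("gen"))
                if not gm:
                    raise PatternSyntaxError(
                        f"cannot parse generator {m.group('gen')!r}")
                gen = CreateExpression("?" + gm.group("base"),
                                       gm.group("suffix"))
            var = PatternVariable("?" + m.group("name"), m.group("kind"), gen)
            if var.name in pattern.variables:
                raise PatternSyntaxError(
                    f"duplicate variable {var.name!r}")
            pattern.variables[var.name] = var
        else:
            m = _ADD_RE.match(line)
            if not m:
                raise UnsupportedConstructError(
                    f"only ADD statements are supported, got {line!r}")
            pattern.statements.append(_parse_statement(m.group("body")))
    if not saw_end:
        raise PatternSyntaxError("pattern body is not closed with END;")
    pattern.check_invariants()
    return pattern


# ---------------------------------------------------------------------------
# Variable classification
# ---------------------------------------------------------------------------

def _typed_named_class(pattern: Pattern, var: str) -> Optional[str]:
    """First named class this variable is typed with by an instanceOf."""
    for st in pattern.statements:
        if st.form == "instanceOf" and st.subject == var:
            ast = st.payload[0]
            stack = [ast]
            while stack:
                node = stack.pop(0)
                if node[0] == "name":
                    return node[1]
                if node[0] == "and":
                    stack = list(node[1]) + stack
    return None


def classify_variables(pattern: Pattern, binding: PatternBinding
                       ) -> tuple[set[str], set[str]]:
    """Split variables into (creating, referencing).

    Creating: INDIVIDUAL variables that carry a create() generator, are
    bound to an attribute path (the path value becomes the URI token), or
    are free but typed by an instanceOf statement (minted fresh).
    Referencing: variables bound to already-transformed source entities.
    CONSTANT variables are never creating.
    """
    creating: set[str] = set()
    referencing: set[str] = set()
    for var in pattern.variables.values():
        if var.kind == "CONSTANT":
            target = binding.bind.get(var.name)
            if target is None or not target.path:
                raise ClassificationError(
                    f"CONSTANT variable {var.name} must be bound to an "
                    "attribute path")
            continue
        target = binding.bind.get(var.name)
        if var.generator is not None:
            creating.add(var.name)
        elif target is not None and target.path:
            creating.add(var.name)
        elif target is not None and target.entity:
            referencing.add(var.name)
        elif _typed_named_class(pattern, var.name) is not None:
            creating.add(var.name)
        else:
            raise ClassificationError(
                f"INDIVIDUAL variable {var.name} is unbound, generator-free "
                "and never typed")
    return creating, referencing


# ---------------------------------------------------------------------------
# Instantiation
# ---------------------------------------------------------------------------

def _resolve_expr(ast, onto: OntologyModel):
    if ast[0] == "name":
        return ClassRef(onto.expand_prefixed(ast[1]))
    if ast[0] == "some":
        return Existential(onto.expand_prefixed(ast[1]),
                           onto.expand_prefixed(ast[2]))
    return Intersection(tuple(_resolve_expr(o, onto) for o in ast[1]))


def _existentials(expr):
    if isinstance(expr, Existential):
        yield expr
    elif isinstance(expr, Intersection):
        for op in expr.operands:
            yield from _existentials(op)


class SkipInstantiation(Exception):
    """Internal signal: this instance cannot satisfy the pattern."""


def instantiate_pattern(pattern: Pattern, binding: PatternBinding,
                        context: dict[str, DataInstance],
                        registry: dict,
                        policy: URIPolicy,
                        onto: OntologyModel,
                        log: Optional[list] = None) -> Optional[AxiomBatch]:
    """Instantiate one pattern for one anchor instance context.

    ``context`` maps entity names to the instances bound for this
    application (the anchor plus its link-connected relatives);
    ``registry`` maps ``(source_id, entity, local_id)`` to the individuals
    already produced by entity rules.  Returns None (with a log entry) when
    a CONSTANT path resolves to no value or a referenced individual is
    missing — the instance cannot satisfy congruence for this pattern.
    """
    creating, referencing = classify_variables(pattern, binding)
    values: dict[str, object] = {}
    anchor = context.get(binding.anchor_entity())

    def note(action: str, detail: str) -> None:
        if log is not None:
            inst = anchor
            log.append({"phase": "pattern", "pattern": pattern.name,
                        "source_id": inst.source_id if inst else "",
                        "entity": inst.entity if inst else "",
                        "local_id": inst.local_id if inst else "",
                        "action": action, "detail": detail})
        logger.debug("pattern %s: %s (%s)", pattern.name, action, detail)

    try:
        # CONSTANT variables first: their absence skips the whole application
        for var in pattern.variables.values():
            if var.kind != "CONSTANT":
                continue
            target = binding.bind[var.name]
            inst = context.get(target.entity)
            if inst is None:
                note("skip", f"no instance of {target.entity!r} in context")
                raise SkipInstantiation
            vals = resolve_path(inst, target.path)
            if not vals:
                note("skip",
                     f"CONSTANT {var.name} path {target.path!r} resolved "
                     "to no value")
                raise SkipInstantiation
            values[var.name] = vals

        # referencing INDIVIDUALs
        for name in sorted(referencing):
            target = binding.bind[name]
            inst = context.get(target.entity)
            if inst is None:
                note("skip", f"no instance of {target.entity!r} in context")
                raise SkipInstantiation
            inds = registry.get((inst.source_id, inst.entity, inst.local_id),
                                [])
            wanted = _typed_named_class(pattern, name)
            chosen = None
            if wanted is not None:
                wanted_uri = onto.expand_prefixed(wanted)
                for ind in inds:
                    if wanted_uri in ind.named_classes():
                        chosen = ind
                        break
            if chosen is None and inds:
                chosen = inds[0]
            if chosen is None:
                note("skip", f"referenced individual missing for {name} "
                     f"({target.entity}/{inst.local_id})")
                raise SkipInstantiation
            values[name] = chosen

        # creating INDIVIDUALs: path-bound and fresh first, create() after
        new_individuals: list[Individual] = []

        def make(name: str, token: str, prov_inst) -> Individual:
            cls_name = _typed_named_class(pattern, name)
            if cls_name is None:
                raise ClassificationError(
                    f"creating variable {name} is never typed")
            cls = ClassRef(onto.expand_prefixed(cls_name))
            ind = Individual(uri=mint_uri(policy, cls, token), token=token)
            ind.add_class(cls)
            if prov_inst is not None:
                ind.add_provenance(prov_inst.source_id, prov_inst.entity,
                                   prov_inst.local_id)
            new_individuals.append(ind)
            return ind

        pending = [pattern.variables[n] for n in pattern.variables
                   if n in creating]
        progress = True
        while pending and progress:
            progress = False
            still = []
            for var in pending:
                if var.generator is not None:
                    base = values.get(var.generator.base_variable)
                    if base is None:
                        still.append(var)
                        continue
                    token = base.token + var.generator.suffix
                    values[var.name] = make(var.name, token, anchor)
                else:
                    target = binding.bind.get(var.name)
                    if target is not None and target.path:
                        inst = context.get(target.entity)
                        if inst is None:
                            note("skip", f"no instance of {target.entity!r}")
                            raise SkipInstantiation
                        vals = resolve_path(inst, target.path)
                        if not vals:
                            note("skip",
                                 f"{var.name} path {target.path!r} resolved "
                                 "to no value")
                            raise SkipInstantiation
                        values[var.name] = make(var.name, vals[0], inst)
                    else:
                        # minted fresh, deterministic per anchor instance
                        token = (f"{anchor.local_id}_{var.name[1:]}"
                                 if anchor is not None else var.name[1:])
                        values[var.name] = make(var.name, token, anchor)
                progress = True
            pending = still
        if pending:
            raise ClassificationError(
                f"unresolvable create() dependency for "
                f"{[v.name for v in pending]}")
    except SkipInstantiation:
        return None

    batch = AxiomBatch(new_individuals=new_individuals)

    def subject_of(name: str) -> Individual:
        val = values[name]
        if not isinstance(val, Individual):
            raise ClassificationError(
                f"{name} does not denote an individual")
        return val

    for st in pattern.statements:
        subj = subject_of(st.subject)
        if st.form == "instanceOf":
            expr = _resolve_expr(st.payload[0], onto)
            for uri in sorted(
                    {c for c in _named_class_uris(expr)}):
                batch.assertions.append(("class", subj.uri, ClassRef(uri)))
            if not isinstance(expr, ClassRef):
                batch.assertions.append(("class", subj.uri, expr))
            for ex in _existentials(expr):
                filler_cls = ClassRef(ex.filler_uri)
                token = f"{subj.token}_{local_name(ex.property_uri)}"
                filler = Individual(
                    uri=mint_uri(policy, filler_cls, token), token=token)
                filler.add_class(filler_cls)
                if anchor is not None:
                    filler.add_provenance(anchor.source_id, anchor.entity,
                                          anchor.local_id)
                if filler.uri not in {i.uri for i in batch.new_individuals}:
                    batch.new_individuals.append(filler)
                batch.assertions.append(
                    ("object", subj.uri, ex.property_uri, filler.uri))
        elif st.form == "object":
            prop_uri = onto.expand_prefixed(st.payload[0])
            operand = st.payload[1]
            var = pattern.variables.get(operand)
            if var is not None and var.kind == "CONSTANT":
                decl = onto.datatype_properties.get(prop_uri)
                dtype = decl.range if decl and decl.range else XSD_STRING
                for v in values[operand]:
                    batch.assertions.append(
                        ("data", subj.uri, prop_uri, v, dtype))
            else:
                obj = subject_of(operand)
                batch.assertions.append(("object", subj.uri, prop_uri,
                                         obj.uri))
        else:  # data with literal
            prop_uri = onto.expand_prefixed(st.payload[0])
            decl = onto.datatype_properties.get(prop_uri)
            dtype = decl.range if decl and decl.range else XSD_STRING
            lit = st.payload[1][1]
            batch.assertions.append(("data", subj.uri, prop_uri, lit, dtype))
    return batch


def _named_class_uris(expr) -> set[str]:
    from .ontology_kb import named_parts
    return named_parts(expr)
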