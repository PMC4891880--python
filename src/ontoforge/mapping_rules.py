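"""The three basic mapping-rule types, their dialect, and their application.

* ``entity_rule(S, T[, c1])`` — every instance of schema entity S
  satisfying the optional condition c1 yields a congruent individual of
  ontology class T.
* ``attribute_rule((S, A1), (T, A2))`` — the value of attribute A1 becomes
  the value of datatype property A2 on the congruent individual, lexically
  identical ("A1 and A2 have the same value").
* ``relation_rule((S1, R1, S2), (T1, R2, T2))`` — instances linked through
  schema relation R1 yield individuals linked through object property R2.

Rules are written in a declarative YAML dialect (there is no standard
language for schema-to-ontology mappings, so this package defines a small,
diff-friendly one).  One document carries the rules, the pattern bindings,
the identity rules, external sameAs link declarations and the URI policy::

    prefixes: {ex: "http://example.org/onto#"}
    entity_rules:
      - {source: gene, target: ex:Gene}
    attribute_rules:
      - source: {entity: gene, path: "@geneId"}
        target: {class: ex:Gene, property: ex:Identifier}
    relation_rules:
      - source: {subject: gene, relation: "database/gene", object: database}
        target: {subject: ex:Gene, property: ex:contained_in,
                 object: ex:Database}

Conditions are existential over multi-valued paths: the rule fires when
*any* resolved value satisfies the comparator after value-kind coercion; a
coercion failure is a logged non-match, and an empty resolution is false.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from typing import Optional

import yaml

from .errors import MappingSyntaxError, UnknownTermError
from .identity_engine import IdentityRule
from .ontology_kb import (
    ClassRef,
    Individual,
    KnowledgeBase,
    OntologyModel,
    PropertyRef,
    URIPolicy,
    XSD_STRING,
    mint_uri,
)
from .pattern_engine import BindingTarget, PatternBinding
from .schema_model import (
    DataInstance,
    InputSchema,
    canonical_path,
    coerce_value,
    resolve_path,
)
from .errors import CoercionError, PathSyntaxError

logger = logging.getLogger("ontoforge")

_COMPARATORS = ("eq", "ne", "lt", "le", "gt", "ge")
_ORDERING = ("lt", "le", "gt", "ge")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Condition:
    attribute_path: str
    comparator: str
    literal: str
    value_kind: str = "text"

    def __post_init__(self):
        if self.comparator not in _COMPARATORS:
            raise MappingSyntaxError(
                f"unknown comparator {self.comparator!r}")
        if self.comparator in _ORDERING and \
                self.value_kind not in ("integer", "decimal"):
            raise MappingSyntaxError(
                f"ordering comparator {self.comparator!r} requires a "
                "numeric value kind")


@dataclass
class EntityRule:
    id: str
    source_entity: str
    target_class: str                  # prefixed name or URI
    condition: Optional[Condition] = None
    uri_token_path: Optional[str] = None
    target_ref: Optional[ClassRef] = None   # filled by validate_mapping


@dataclass
class AttributeRule:
    id: str
    source_entity: str
    source_path: str
    target_class: str
    target_property: str
    target_class_ref: Optional[ClassRef] = None
    target_property_ref: Optional[PropertyRef] = None


@dataclass
class RelationRule:
    id: str
    source_subject: str      # S1
    source_relation: str     # R1 (schema relation name)
    source_object: str       # S2
    target_subject: str      # T1
    target_property: str     # R2
    target_object: str       # T2
    refs: dict = field(default_factory=dict)   # resolved URIs


@dataclass
class ExternalLink:
    entity: str
    base: str
    token_path: str


@dataclass
class MappingRuleSet:
    entity_rules: list[EntityRule] = field(default_factory=list)
    attribute_rules: list[AttributeRule] = field(default_factory=list)
    relation_rules: list[RelationRule] = field(default_factory=list)
    pattern_bindings: list[PatternBinding] = field(default_factory=list)
    external_links: list[ExternalLink] = field(default_factory=list)
    identity_rules: list[dict] = field(default_factory=list)  # raw decls
    uri_policy_decl: dict = field(default_factory=dict)
    prefixes: dict[str, str] = field(default_factory=dict)

    def entity_rules_for(self, entity: str) -> list[EntityRule]:
        return [r for r in self.entity_rules if r.source_entity == entity]

    def has_entity_rule(self, entity: str, target_class: str) -> bool:
        return any(r.source_entity == entity and
                   r.target_class == target_class
                   for r in self.entity_rules)


@dataclass
class ValidationReport:
    problems: list[str] = field(default_factory=list)

    @property
    def empty(self) -> bool:
        return not self.problems

    def add(self, message: str) -> None:
        self.problems.append(message)

    def to_json(self) -> str:
        return json.dumps(self.problems, indent=2)


# ---------------------------------------------------------------------------
# Parsing the dialect
# ---------------------------------------------------------------------------

def _parse_condition(raw) -> Optional[Condition]:
    if raw is None:
        return None
    if not isinstance(raw, dict) or "path" not in raw:
        raise MappingSyntaxError(f"cannot parse condition {raw!r}")
    return Condition(
        attribute_path=raw["path"],
        comparator=raw.get("op", "eq"),
        literal=str(raw.get("value", "")),
        value_kind=raw.get("kind", "text"))


def parse_mapping_document(document: str) -> MappingRuleSet:
    """Parse a mapping document in the dialect into a rule set.

    Name resolution against the schema and ontology is deferred to
    :func:`validate_mapping`; only well-formedness is enforced here.
    Duplicate rule identifiers are an error.
    """
    try:
        data = yaml.safe_load(document)
    except yaml.MarkedYAMLError as exc:
        mark = exc.problem_mark
        line = mark.line + 1 if mark else "?"
        raise MappingSyntaxError(
            f"mapping syntax error at line {line}: {exc.problem}") from exc
    except yaml.YAMLError as exc:
        raise MappingSyntaxError(f"mapping syntax error: {exc}") from exc
    if data is None:
        return MappingRuleSet()
    if not isinstance(data, dict):
        raise MappingSyntaxError("mapping document must be a mapping block")

    rules = MappingRuleSet()
    rules.prefixes = dict(data.get("prefixes") or {})
    seen_ids: set[str] = set()

    def claim(rule_id: str) -> str:
        if rule_id in seen_ids:
            raise MappingSyntaxError(f"duplicate rule identifier {rule_id!r}")
        seen_ids.add(rule_id)
        return rule_id

    for i, raw in enumerate(data.get("entity_rules") or []):
        rid = claim(raw.get("id") or
                    f"entity:{raw.get('source')}->{raw.get('target')}")
        rules.entity_rules.append(EntityRule(
            id=rid, source_entity=raw["source"], target_class=raw["target"],
            condition=_parse_condition(raw.get("condition")),
            uri_token_path=raw.get("uri_token")))
    for raw in data.get("attribute_rules") or []:
        src, tgt = raw["source"], raw["target"]
        rid = claim(raw.get("id") or
                    f"attr:{src['entity']}/{src['path']}->"
                    f"{tgt['class']}.{tgt['property']}")
        rules.attribute_rules.append(AttributeRule(
            id=rid, source_entity=src["entity"], source_path=src["path"],
            target_class=tgt["class"], target_property=tgt["property"]))
    for raw in data.get("relation_rules") or []:
        src, tgt = raw["source"], raw["target"]
        rid = claim(raw.get("id") or
                    f"rel:{src['subject']}-{src['relation']}-"
                    f"{src['object']}")
        rules.relation_rules.append(RelationRule(
            id=rid,
            source_subject=src["subject"], source_relation=src["relation"],
            source_object=src["object"],
            target_subject=tgt["subject"],
            target_property=tgt["property"],
            target_object=tgt["object"]))
    for raw in data.get("patterns") or []:
        bind = {}
        for var, spec in (raw.get("bind") or {}).items():
            if isinstance(spec, str):
                bind[var] = BindingTarget(entity=spec)
            else:
                bind[var] = BindingTarget(entity=spec.get("entity"),
                                          path=spec.get("path"))
        rules.pattern_bindings.append(PatternBinding(
            pattern=raw["pattern"], bind=bind, anchor=raw.get("anchor")))
    for raw in data.get("identity_rules") or []:
        rules.identity_rules.append(dict(raw))
    for raw in data.get("external_links") or []:
        rules.external_links.append(ExternalLink(
            entity=raw["entity"], base=raw["base"],
            token_path=raw["token"]))
    rules.uri_policy_decl = dict(data.get("uri_policy") or {})
    return rules


def build_uri_policy(rules: MappingRuleSet,
                     onto: OntologyModel) -> URIPolicy:
    """Materialize the URI policy declared in the mapping document."""
    decl = rules.uri_policy_decl
    policy = URIPolicy(default_base=decl.get(
        "default_base", "http://example.org/data/"))
    for name, spec in (decl.get("per_class") or {}).items():
        uri = onto.expand_prefixed(name)
        if isinstance(spec, str):
            policy.per_class_base[uri] = spec
        else:
            policy.per_class_base[uri] = spec["base"]
            if spec.get("mode"):
                policy.mode[uri] = spec["mode"]
    return policy


def build_identity_rules(rules: MappingRuleSet,
                         onto: OntologyModel) -> list[IdentityRule]:
    """Resolve the identity-rule declarations against the ontology."""
    out = []
    for raw in rules.identity_rules:
        out.append(IdentityRule(
            target_class=onto.expand_prefixed(raw["class"]),
            identity_properties=[onto.expand_prefixed(p)
                                 for p in raw["properties"]],
            behaviour=raw.get("behaviour", "merge"),
            merged_uri_policy=raw.get("merged_uri_policy", "first-wins"),
            fresh_prefix=raw.get("fresh_prefix")))
    return out


# ---------------------------------------------------------------------------
# Validation (also binds resolved ontology references onto the rules)
# ---------------------------------------------------------------------------

def validate_mapping(rules: MappingRuleSet, schema: InputSchema,
                     onto: OntologyModel) -> ValidationReport:
    """Check referential closure of the rule set; bind resolved references.

    An empty report is required before a transformation may run.
    """
    report = ValidationReport()
    # extra prefixes declared in the mapping complement the ontology's
    for p, ns in rules.prefixes.items():
        onto.prefixes.setdefault(p, ns)

    def resolve_class(name: str, where: str) -> Optional[ClassRef]:
        try:
            uri = onto.expand_prefixed(name)
        except UnknownTermError as exc:
            report.add(f"{where}: {exc}")
            return None
        if uri not in onto.classes:
            report.add(f"{where}: unknown ontology class {name!r}")
            return None
        return onto.classes[uri]

    def resolve_property(name: str, where: str) -> Optional[PropertyRef]:
        try:
            uri = onto.expand_prefixed(name)
        except UnknownTermError as exc:
            report.add(f"{where}: {exc}")
            return None
        prop = onto.property(uri)
        if prop is None:
            report.add(f"{where}: unknown ontology property {name!r}")
        return prop

    def check_path(entity: str, path: str, where: str) -> None:
        try:
            canon = canonical_path(path)
        except PathSyntaxError as exc:
            report.add(f"{where}: {exc}")
            return
        ent = schema.entities.get(entity)
        if ent is not None and canon not in ent.attributes:
            report.add(f"{where}: unknown attribute path {path!r} on "
                       f"entity {entity!r}")

    for rule in rules.entity_rules:
        where = f"entity rule {rule.id}"
        if rule.source_entity not in schema.entities:
            report.add(f"{where}: unknown schema entity "
                       f"{rule.source_entity!r}")
        rule.target_ref = resolve_class(rule.target_class, where)
        if rule.condition is not None:
            check_path(rule.source_entity, rule.condition.attribute_path,
                       where)
            try:
                Condition(**vars(rule.condition))
            except MappingSyntaxError as exc:
                report.add(f"{where}: {exc}")
            if rule.condition.comparator in _ORDERING:
                try:
                    coerce_value(rule.condition.value_kind,
                                 rule.condition.literal)
                except CoercionError as exc:
                    report.add(f"{where}: condition literal {exc}")
        if rule.uri_token_path:
            check_path(rule.source_entity, rule.uri_token_path, where)

    for rule in rules.attribute_rules:
        where = f"attribute rule {rule.id}"
        if rule.source_entity not in schema.entities:
            report.add(f"{where}: unknown schema entity "
                       f"{rule.source_entity!r}")
        else:
            check_path(rule.source_entity, rule.source_path, where)
        rule.target_class_ref = resolve_class(rule.target_class, where)
        prop = resolve_property(rule.target_property, where)
        if prop is not None:
            if prop.kind != "datatype":
                report.add(f"{where}: {rule.target_property!r} is not a "
                           "datatype property")
            else:
                rule.target_property_ref = prop
        if not rules.has_entity_rule(rule.source_entity, rule.target_class):
            report.add(f"{where}: no entity rule for "
                       f"({rule.source_entity}, {rule.target_class})")

    for rule in rules.relation_rules:
        where = f"relation rule {rule.id}"
        rel = schema.relations.get(rule.source_relation)
        if rel is None:
            report.add(f"{where}: unknown schema relation "
                       f"{rule.source_relation!r}")
        else:
            ends = {rel.source_entity, rel.target_entity}
            if {rule.source_subject, rule.source_object} != ends:
                report.add(f"{where}: relation {rule.source_relation!r} "
                           f"does not connect {rule.source_subject!r} and "
                           f"{rule.source_object!r}")
        t1 = resolve_class(rule.target_subject, where)
        t2 = resolve_class(rule.target_object, where)
        prop = resolve_property(rule.target_property, where)
        if prop is not None and prop.kind != "object":
            report.add(f"{where}: {rule.target_property!r} is not an "
                       "object property")
        for ent, cls in ((rule.source_subject, rule.target_subject),
                         (rule.source_object, rule.target_object)):
            if not rules.has_entity_rule(ent, cls):
                report.add(f"{where}: no entity rule for ({ent}, {cls})")
        if t1 and t2 and prop:
            rule.refs = {"t1": t1.uri, "t2": t2.uri, "r2": prop.uri}

    for binding in rules.pattern_bindings:
        where = f"pattern binding {binding.pattern}"
        for var, target in binding.bind.items():
            if target.entity and target.entity not in schema.entities:
                report.add(f"{where}: unknown entity {target.entity!r} "
                           f"bound to {var}")
            elif target.entity and target.path:
                check_path(target.entity, target.path, f"{where} ({var})")

    for link in rules.external_links:
        where = f"external link for {link.entity}"
        if link.entity not in schema.entities:
            report.add(f"{where}: unknown schema entity")
        else:
            check_path(link.entity, link.token_path, where)

    for raw in rules.identity_rules:
        where = f"identity rule for {raw.get('class')}"
        resolve_class(str(raw.get("class")), where)
        for p in raw.get("properties") or []:
            resolve_property(p, where)
        if not raw.get("properties"):
            report.add(f"{where}: empty identity property set")
    return report


# ---------------------------------------------------------------------------
# Rule application
# ---------------------------------------------------------------------------

def evaluate_condition(cond: Condition, instance: DataInstance) -> bool:
    """Existential condition check: any resolved value satisfying the
    comparator (after value-kind coercion) makes the condition true."""
    values = resolve_path(instance, cond.attribute_path)
    try:
        rhs = coerce_value(cond.value_kind, cond.literal)
    except CoercionError:
        logger.warning("condition literal %r not a valid %s; non-match",
                       cond.literal, cond.value_kind)
        return False
    for raw in values:
        try:
            lhs = coerce_value(cond.value_kind, raw)
        except CoercionError:
            logger.warning("condition value %r not a valid %s; non-match",
                           raw, cond.value_kind)
            continue
        if _compare(lhs, cond.comparator, rhs):
            return True
    return False


def _compare(lhs, op, rhs) -> bool:
    return {"eq": lhs == rhs, "ne": lhs != rhs, "lt": lhs < rhs,
            "le": lhs <= rhs, "gt": lhs > rhs, "ge": lhs >= rhs}[op]


def apply_entity_rule(rule: EntityRule, instance: DataInstance,
                      kb: KnowledgeBase, policy: URIPolicy
                      ) -> Optional[Individual]:
    """Produce the congruent individual for one instance.

    Returns None (skip signal) when the rule's condition is not satisfied.
    The individual is NOT yet added to the KB: the engine admits it after
    pattern content, identity resolution and the consistency gate.
    """
    if rule.condition is not None and \
            not evaluate_condition(rule.condition, instance):
        return None
    if rule.target_ref is None:
        raise UnknownTermError(
            f"entity rule {rule.id} was not validated (no target class)")
    token = instance.local_id
    if rule.uri_token_path:
        vals = resolve_path(instance, rule.uri_token_path)
        if vals:
            token = vals[0]
        else:
            logger.warning(
                "entity rule %s: URI token path %r empty on %s/%s; "
                "falling back to local id", rule.id, rule.uri_token_path,
                instance.entity, instance.local_id)
    ind = Individual(uri=mint_uri(policy, rule.target_ref, token),
                     token=token)
    ind.add_class(rule.target_ref)
    ind.add_provenance(instance.source_id, instance.entity,
                       instance.local_id)
    return ind


def apply_attribute_rule(rule: AttributeRule, instance: DataInstance,
                         individual: Individual) -> list[tuple]:
    """Data assertions for one instance: one per resolved value, lexically
    identical to the source value, typed by A2's declared range."""
    prop = rule.target_property_ref
    if prop is None:
        raise UnknownTermError(
            f"attribute rule {rule.id} was not validated")
    dtype = prop.range if prop.range else XSD_STRING
    out = []
    for value in resolve_path(instance, rule.source_path):
        out.append(("data", individual.uri, prop.uri, value, dtype))
    return out


def apply_relation_rule(rule: RelationRule,
                        link: tuple[DataInstance, DataInstance],
                        registry: dict) -> Optional[tuple]:
    """Object assertion (t1, R2, t2) for one source link, or None when a
    counterpart individual is missing (skipped or rejected upstream)."""
    if not rule.refs:
        raise UnknownTermError(f"relation rule {rule.id} was not validated")
    s1, s2 = link

    def find(inst: DataInstance, class_uri: str) -> Optional[Individual]:
        for ind in registry.get((inst.source_id, inst.entity,
                                 inst.local_id), []):
            if class_uri in ind.named_classes():
                return ind
        return None

    t1 = find(s1, rule.refs["t1"])
    t2 = find(s2, rule.refs["t2"])
    if t1 is None or t2 is None:
        logger.info("relation rule %s withheld: missing counterpart for "
                    "(%s/%s, %s/%s)", rule.id, s1.entity, s1.local_id,
                    s2.entity, s2.local_id)
        return None
    return ("object", t1.uri, rule.refs["r2"], t2.uri)
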