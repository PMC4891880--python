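"""Orchestration of one transformation run and of multi-source integration.

The engine enforces the method's execution order:

1. basic entity rules run, producing the set I of candidate individuals;
2. the pattern statements that create new individuals run, and those
   individuals join I;
3. then, per candidate: (a) the remaining pattern statements, (b) the
   attribute rules, (c) the relation rules, and finally (d) the identity
   rules, which decide unique / merge / link / reject-incomplete.

Before admission every candidate's whole batch (class memberships, pattern
content, data and object assertions) passes the structural consistency
gate; an inconsistent batch is discarded whole, with a logged violation.
Because all candidates exist before step 3 begins, relation assertions can
point forward in document order; a repair pass afterwards rewrites
assertions whose target was merged away and withdraws those whose target
was rejected, logging every repair.
"""

from __future__ import annotations

import logging
import urllib.parse
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .errors import AmbiguousIdentityError, OntoforgeError, RefuseToRunError
from .identity_engine import (
    IdentityRule,
    applies_to,
    identity_key,
    link_individuals,
    merge_individuals,
    resolve_identity,
)
from .mapping_rules import (
    MappingRuleSet,
    apply_attribute_rule,
    apply_entity_rule,
    apply_relation_rule,
    evaluate_condition,
    validate_mapping,
)
from .ontology_kb import (
    AxiomBatch,
    Individual,
    KnowledgeBase,
    OntologyModel,
    URIPolicy,
    assert_axioms,
    check_consistency,
)
from .pattern_engine import Pattern, instantiate_pattern
from .schema_model import DataInstance, InputSchema, resolve_path

logger = logging.getLogger("ontoforge")


@dataclass
class RunConfig:
    profile: str = "rdf"                  # rdf | owl
    serialization: str = "turtle"         # turtle | rdfxml
    emit_different_from: bool = False
    strict_reading: bool = True
    reasoner_hook: Optional[list] = None  # external command, if any
    uri_policy: URIPolicy = field(default_factory=URIPolicy)
    random_seed: int = 0                  # reserved for sampling tie-breaks

    def __post_init__(self):
        if self.profile not in ("rdf", "owl"):
            raise ValueError(f"unknown profile {self.profile!r}")
        if self.serialization not in ("turtle", "rdfxml"):
            raise ValueError(
                f"unknown serialization {self.serialization!r}")


@dataclass
class _Candidate:
    individual: Individual
    instance: Optional[DataInstance]
    entity_rule: object = None        # EntityRule for rule-born candidates
    origin: str = "entity-rule"


@dataclass
class TransformResult:
    kb: KnowledgeBase
    individuals: list = field(default_factory=list)   # admitted Individuals
    log: list = field(default_factory=list)           # ordered decisions
    stats: dict = field(default_factory=dict)
    # audit context
    uri_final: dict = field(default_factory=dict)     # candidate uri -> final
    registry: dict = field(default_factory=dict)
    instances: list = field(default_factory=list)
    rules: Optional[MappingRuleSet] = None
    schema: Optional[InputSchema] = None
    final_report: object = None

    def log_lines(self) -> str:
        import json
        return "\n".join(json.dumps(rec, sort_keys=True) for rec in self.log)


def compute_stats(log: list, kb: KnowledgeBase) -> dict:
    """Counts recomputed from the decision log plus the KB (audit)."""
    stats: dict = {"actions": {}, "individuals": len(kb.individuals),
                   "same_as_pairs": len(kb.same_as),
                   "different_from_pairs": len(kb.different_from),
                   "per_class": {}}
    for rec in log:
        action = rec.get("action", "?")
        stats["actions"][action] = stats["actions"].get(action, 0) + 1
    for ind in kb.individuals.values():
        for cls in sorted(ind.named_classes()):
            stats["per_class"][cls] = stats["per_class"].get(cls, 0) + 1
    return stats


def _adjacency(instances: list, schema: InputSchema):
    by_key = {(i.entity, i.local_id): i for i in instances}
    adj: dict[tuple, list] = {}
    for inst in instances:
        for rel_name, target_lid in inst.links:
            rel = schema.relations.get(rel_name)
            if rel is None:
                continue
            tgt = by_key.get((rel.target_entity, target_lid))
            if tgt is None:
                continue
            adj.setdefault((inst.entity, inst.local_id), []).append(tgt)
            adj.setdefault((tgt.entity, tgt.local_id), []).append(inst)
    return by_key, adj


def _related(anchor: DataInstance, entity: str, adj) -> Optional[DataInstance]:
    """Nearest link-connected instance of ``entity`` (BFS, both directions)."""
    if anchor.entity == entity:
        return anchor
    seen = {(anchor.entity, anchor.local_id)}
    queue = [anchor]
    while queue:
        cur = queue.pop(0)
        for nxt in adj.get((cur.entity, cur.local_id), []):
            key = (nxt.entity, nxt.local_id)
            if key in seen:
                continue
            if nxt.entity == entity:
                return nxt
            seen.add(key)
            queue.append(nxt)
    return None


def transform(schema: InputSchema, instances: Iterable[DataInstance],
              rules: MappingRuleSet, patterns: dict[str, Pattern],
              identity_rules: list[IdentityRule], onto: OntologyModel,
              config: RunConfig, kb: Optional[KnowledgeBase] = None,
              source_id: Optional[str] = None,
              _finalize: bool = True) -> TransformResult:
    """Transform one source into (a shared or fresh) knowledge base."""
    report = validate_mapping(rules, schema, onto)
    if not report.empty:
        raise RefuseToRunError(
            "mapping validation failed:\n" + "\n".join(report.problems))
    for binding in rules.pattern_bindings:
        if binding.pattern not in patterns:
            raise RefuseToRunError(
                f"pattern {binding.pattern!r} bound but not provided")

    policy = config.uri_policy
    if kb is None:
        kb = KnowledgeBase(ontology=onto)
    instances = list(instances)
    if source_id is None:
        source_id = instances[0].source_id if instances else "source"
    by_key, adj = _adjacency(instances, schema)
    log: list[dict] = []

    def note(phase, action, inst=None, detail=""):
        log.append({"phase": phase, "source_id": source_id,
                    "entity": inst.entity if inst else "",
                    "local_id": inst.local_id if inst else "",
                    "action": action, "detail": detail})

    note("run", "start", detail=f"{len(instances)} instances")

    # ---- step 1: basic entity rules -----------------------------------
    candidates: list[_Candidate] = []
    registry: dict[tuple, list[Individual]] = {}
    for inst in instances:
        for rule in rules.entity_rules:
            if rule.source_entity != inst.entity:
                continue
            if rule.condition is not None and \
                    not evaluate_condition(rule.condition, inst):
                note("entity-rules", "skip-condition", inst,
                     f"rule {rule.id}")
                continue
            ind = apply_entity_rule(rule, inst, kb, policy)
            candidates.append(_Candidate(ind, inst, entity_rule=rule))
            registry.setdefault(
                (inst.source_id, inst.entity, inst.local_id), []).append(ind)
            note("entity-rules", "candidate", inst,
                 f"{rule.id} -> {ind.uri}")

    # ---- step 2: creating pattern statements --------------------------
    pattern_assertions: dict[str, list] = {}
    for binding in rules.pattern_bindings:
        pattern = patterns[binding.pattern]
        anchor_entity = binding.anchor_entity()
        needed = sorted({t.entity for t in binding.bind.values() if t.entity})
        for inst in instances:
            if inst.entity != anchor_entity:
                continue
            context = {}
            for ent in needed:
                rel_inst = _related(inst, ent, adj)
                if rel_inst is not None:
                    context[ent] = rel_inst
            batch = instantiate_pattern(pattern, binding, context, registry,
                                        policy, onto, log)
            if batch is None:
                continue
            known_uris = {c.individual.uri for c in candidates}
            for ind in batch.new_individuals:
                candidates.append(_Candidate(
                    ind, inst, origin=f"pattern:{pattern.name}"))
                if ind.provenance:
                    registry.setdefault(tuple(ind.provenance[0]),
                                        []).append(ind)
                if ind.uri not in known_uris:
                    note("patterns", "candidate", inst,
                         f"{pattern.name} -> {ind.uri}")
            for a in batch.assertions:
                pattern_assertions.setdefault(a[1], []).append(a)

    # ---- step 3: per-candidate content, gate, identity -----------------
    uri_final: dict[str, Optional[str]] = {}
    admitted: list[Individual] = []

    def remap_final(old: str, new: str) -> None:
        for k, v in uri_final.items():
            if v == old:
                uri_final[k] = new

    for cand in candidates:
        ind, inst = cand.individual, cand.instance
        # (3a) remaining pattern statements
        for a in pattern_assertions.get(ind.uri, []):
            if a[0] == "class":
                ind.add_class(a[2])
            elif a[0] == "data":
                ind.add_data(a[2], a[3], a[4])
            else:
                ind.add_object(a[2], a[3])
        # (3b) attribute rules
        if cand.entity_rule is not None:
            for arule in rules.attribute_rules:
                if arule.source_entity == inst.entity and \
                        arule.target_class == cand.entity_rule.target_class:
                    for a in apply_attribute_rule(arule, inst, ind):
                        ind.add_data(a[2], a[3], a[4])
        # (3c) relation rules with this candidate as subject
        if cand.entity_rule is not None:
            for rrule in rules.relation_rules:
                if rrule.source_subject != inst.entity or \
                        rrule.target_subject != cand.entity_rule.target_class:
                    continue
                rel = schema.relations[rrule.source_relation]
                partners = []
                if rel.source_entity == inst.entity:
                    for rn, lid in inst.links:
                        if rn == rrule.source_relation:
                            p = by_key.get((rel.target_entity, lid))
                            if p is not None:
                                partners.append(p)
                else:
                    for other in instances:
                        if other.entity != rel.source_entity:
                            continue
                        for rn, lid in other.links:
                            if rn == rrule.source_relation and \
                                    lid == inst.local_id:
                                partners.append(other)
                for partner in partners:
                    a = apply_relation_rule(rrule, (inst, partner), registry)
                    if a is None:
                        note("relation-rules", "withheld", inst,
                             f"{rrule.id}: missing counterpart "
                             f"{partner.entity}/{partner.local_id}")
                    elif a[1] == ind.uri:
                        ind.add_object(a[2], a[3])
                    else:
                        pattern_assertions.setdefault(a[1], []).append(a)
        # consistency gate (whole batch)
        batch = AxiomBatch(new_individuals=[ind])
        violations = check_consistency(kb, batch)
        if not violations.empty:
            note("gate", "discard", inst,
                 "; ".join(v.message for v in violations.violations))
            uri_final.setdefault(ind.uri, None)
            continue
        # same-URI identity: one URI, one individual
        if ind.uri in kb.individuals:
            assert_axioms(kb, batch)
            note("identity", "same-uri-union", inst, ind.uri)
            uri_final[ind.uri] = ind.uri
            continue
        # (3d) identity rules
        id_rule = None
        for r in identity_rules:
            if applies_to(ind, r, kb):
                id_rule = r
                break
        if id_rule is None:
            assert_axioms(kb, batch)
            admitted.append(ind)
            uri_final[ind.uri] = ind.uri
            note("identity", "admit", inst, ind.uri)
            continue
        try:
            decision, other = resolve_identity(ind, kb, id_rule)
        except AmbiguousIdentityError as exc:
            note("identity", "reject-ambiguous", inst, str(exc))
            uri_final.setdefault(ind.uri, None)
            continue
        if decision == "reject-incomplete":
            note("identity", "reject-incomplete", inst, ind.uri)
            uri_final.setdefault(ind.uri, None)
        elif decision == "unique":
            assert_axioms(kb, batch)
            admitted.append(ind)
            uri_final[ind.uri] = ind.uri
            note("identity", "admit", inst, ind.uri)
        elif decision == "merge":
            status, final = merge_individuals(kb, other, ind, id_rule)
            if status == "merged":
                if final != other:
                    remap_final(other, final)
                uri_final[ind.uri] = final
                note("identity", "merge", inst, f"{ind.uri} -> {final}")
            elif status == "conflict":
                assert_axioms(kb, batch)
                admitted.append(ind)
                uri_final[ind.uri] = ind.uri
                note("identity", "merge-conflict-kept-distinct", inst,
                     f"{ind.uri} vs {other}")
            else:
                note("identity", "merge-inconsistent-rejected", inst,
                     f"{ind.uri} vs {other}")
                uri_final.setdefault(ind.uri, None)
        else:  # link
            assert_axioms(kb, batch)
            admitted.append(ind)
            uri_final[ind.uri] = ind.uri
            link_individuals(kb, ind.uri, other)
            note("identity", "link", inst, f"{ind.uri} sameAs {other}")

    # ---- repair pass: merged-away or rejected relation targets ---------
    for ind in kb.individuals.values():
        repaired = []
        for prop, obj in ind.object_assertions:
            final = uri_final.get(obj, obj)
            if final is None:
                note("repair", "withdraw",
                     detail=f"{ind.uri} {prop} {obj} (target rejected)")
                continue
            if final != obj:
                note("repair", "rewrite",
                     detail=f"{ind.uri} {prop} {obj} -> {final}")
            if (prop, final) not in repaired:
                repaired.append((prop, final))
        ind.object_assertions = repaired

    # ---- external sameAs links -----------------------------------------
    for cand in candidates:
        if cand.entity_rule is None or cand.instance is None:
            continue
        final = uri_final.get(cand.individual.uri)
        if final is None:
            continue
        for decl in rules.external_links:
            if decl.entity != cand.instance.entity:
                continue
            vals = resolve_path(cand.instance, decl.token_path)
            if not vals:
                note("external-links", "skip", cand.instance,
                     f"token path {decl.token_path!r} empty")
                continue
            ext = decl.base + urllib.parse.quote(vals[0], safe="")
            kb.external_uris.add(ext)
            link_individuals(kb, final, ext)
            note("external-links", "link", cand.instance,
                 f"{final} sameAs {ext}")

    result = TransformResult(kb=kb, individuals=admitted, log=log,
                             uri_final=uri_final, registry=registry,
                             instances=instances, rules=rules, schema=schema)
    if _finalize:
        finalize(result, identity_rules, config)
    result.stats = compute_stats(result.log, kb)
    note("run", "end")
    return result


def finalize(result: TransformResult, identity_rules: list[IdentityRule],
             config: RunConfig) -> None:
    """End-of-run steps: optional differentFrom emission, final check."""
    kb = result.kb
    if config.emit_different_from:
        for rule in identity_rules:
            keyed = []
            for uri in kb.individuals:
                ind = kb.individuals[uri]
                if not applies_to(ind, rule, kb):
                    continue
                try:
                    key = identity_key(ind, rule, kb)
                except AmbiguousIdentityError:
                    continue
                if key is not None:
                    keyed.append((uri, key))
            for i in range(len(keyed)):
                for j in range(i + 1, len(keyed)):
                    if keyed[i][1] != keyed[j][1]:
                        pair = frozenset((keyed[i][0], keyed[j][0]))
                        if pair not in kb.different_from:
                            kb.different_from.append(pair)
    result.final_report = check_consistency(kb)


def integrate(sources: list, patterns: dict[str, Pattern],
              identity_rules: list[IdentityRule], onto: OntologyModel,
              config: RunConfig) -> TransformResult:
    """Transform an ordered set of sources into one shared knowledge base.

    Every source must be mapped against the same ontology; identity rules
    then deduplicate (merge) or interlink (sameAs) equivalent individuals
    across sources.
    """
    kb = KnowledgeBase(ontology=onto)
    combined = TransformResult(kb=kb)
    for idx, (schema, instances, rules) in enumerate(sources):
        res = transform(schema, instances, rules, patterns, identity_rules,
                        onto, config, kb=kb, _finalize=False)
        combined.log.extend(res.log)
        combined.individuals.extend(res.individuals)
        combined.instances.extend(res.instances)
        combined.uri_final.update(res.uri_final)
        combined.registry.update(res.registry)
    finalize(combined, identity_rules, config)
    combined.stats = compute_stats(combined.log, kb)
    return combined


# ---------------------------------------------------------------------------
# Congruence audit
# ---------------------------------------------------------------------------

@dataclass
class CongruenceReport:
    congruent: bool
    failures: list = field(default_factory=list)


def check_congruence(instance: DataInstance, individual_uri: str,
                     rules: MappingRuleSet, kb: KnowledgeBase,
                     result: Optional[TransformResult] = None
                     ) -> CongruenceReport:
    """Verify the congruence relation for one transformed instance.

    (a) every applicable attribute rule's source value appears among the
    individual's data assertions, and every declared link whose
    counterpart was admitted appears as an object assertion (to the
    counterpart's surviving URI); (b) the individual participates in no
    consistency violation.
    """
    ind = kb.individuals.get(individual_uri)
    if ind is None:
        raise OntoforgeError(f"unknown individual {individual_uri!r}")
    failures: list[str] = []
    named = ind.named_classes()
    for arule in rules.attribute_rules:
        if arule.source_entity != instance.entity:
            continue
        if arule.target_class_ref is None or \
                arule.target_class_ref.uri not in named:
            continue
        prop_uri = arule.target_property_ref.uri
        have = {lex for p, lex, _ in ind.data_assertions if p == prop_uri}
        for value in resolve_path(instance, arule.source_path):
            if value not in have:
                failures.append(
                    f"missing data assertion {prop_uri} = {value!r}")
    if result is not None and result.schema is not None:
        by_key = {(i.entity, i.local_id): i for i in result.instances}
        for rrule in rules.relation_rules:
            if rrule.source_subject != instance.entity or \
                    not rrule.refs or rrule.refs["t1"] not in named:
                continue
            rel = result.schema.relations.get(rrule.source_relation)
            if rel is None:
                continue
            if rel.source_entity == instance.entity:
                partner_keys = [(rel.target_entity, lid)
                                for rn, lid in instance.links
                                if rn == rrule.source_relation]
            else:
                partner_keys = [(o.entity, o.local_id)
                                for o in result.instances
                                if o.entity == rel.source_entity
                                and any(rn == rrule.source_relation
                                        and lid == instance.local_id
                                        for rn, lid in o.links)]
            have = {obj for p, obj in ind.object_assertions
                    if p == rrule.refs["r2"]}
            for pk in partner_keys:
                partner = by_key.get(pk)
                if partner is None:
                    continue
                inds = result.registry.get(
                    (partner.source_id, partner.entity, partner.local_id),
                    [])
                expected = None
                for cand in inds:
                    if rrule.refs["t2"] in cand.named_classes():
                        expected = result.uri_final.get(cand.uri)
                        break
                if expected and expected not in have:
                    failures.append(
                        f"missing object assertion {rrule.refs['r2']} -> "
                        f"{expected}")
    report = check_consistency(kb)
    for v in report.violations:
        if any(individual_uri in map(str, a) for a in v.assertions):
            failures.append(f"participates in violation: {v.message}")
    return CongruenceReport(congruent=not failures, failures=failures)


def congruence_sweep(result: TransformResult) -> list:
    """Audit every admitted entity-rule individual of a finished run."""
    out = []
    for key, inds in result.registry.items():
        source_id, entity, local_id = key
        instance = next((i for i in result.instances
                         if i.entity == entity and i.local_id == local_id
                         and i.source_id == source_id), None)
        if instance is None:
            continue
        for ind in inds:
            final = result.uri_final.get(ind.uri)
            if final is None or final not in result.kb.individuals:
                continue
            out.append((instance, final,
                        check_congruence(instance, final, result.rules,
                                         result.kb, result)))
    return out
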