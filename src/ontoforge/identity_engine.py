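"""Identity rules: decide when two individuals denote the same entity.

An identity rule names, for one ontology class C, the set IR of datatype
and object properties whose values univocally identify an individual of C.
Two individuals of C (or of subclasses of C) with equal values for every
property in IR are the same domain entity; the rule's behaviour says
whether the newcomer is *merged* into the existing individual or kept and
*linked* to it with ``owl:sameAs``.

Keys must be complete: an individual missing any IR value yields an
incomplete signal and the corresponding source record is not transformed,
so inconsistency from incomplete data is prevented (patterns may supply
the missing values earlier in the run, which lifts the rejection).
Object-property values are canonicalized through the sameAs closure before
comparison.
"""

from __future__ import annotations

import hashlib
import logging
import urllib.parse
from dataclasses import dataclass
from typing import Optional

from .errors import AmbiguousIdentityError, OntoforgeError, UnknownTermError
from .ontology_kb import (
    AxiomBatch,
    Individual,
    KnowledgeBase,
    check_consistency,
    local_name,
)

logger = logging.getLogger("ontoforge")


@dataclass
class IdentityRule:
    target_class: str                 # class URI (C)
    identity_properties: list[str]    # property URIs (IR), order significant
    behaviour: str = "merge"          # merge | link
    merged_uri_policy: str = "first-wins"   # first-wins | fresh-prefix
    fresh_prefix: Optional[str] = None

    def __post_init__(self):
        if not self.identity_properties:
            raise ValueError("identity rule needs a non-empty property set")
        if self.behaviour not in ("merge", "link"):
            raise ValueError(f"unknown behaviour {self.behaviour!r}")
        if self.merged_uri_policy not in ("first-wins", "fresh-prefix"):
            raise ValueError(
                f"unknown merged URI policy {self.merged_uri_policy!r}")
        if self.merged_uri_policy == "fresh-prefix" and not self.fresh_prefix:
            raise ValueError("fresh-prefix policy needs a prefix")


@dataclass(frozen=True)
class IdentityKey:
    class_uri: str
    items: tuple   # ordered ((property uri, value), ...) — complete

    def digest(self) -> str:
        h = hashlib.sha256(repr((self.class_uri, self.items)).encode())
        return h.hexdigest()[:16]


def applies_to(individual: Individual, rule: IdentityRule,
               kb: KnowledgeBase) -> bool:
    """True when the individual is asserted into C or a subclass of C."""
    for cls in individual.named_classes():
        if rule.target_class in kb.ontology.ancestors(cls):
            return True
    return False


def identity_key(individual: Individual, rule: IdentityRule,
                 kb: KnowledgeBase) -> Optional[IdentityKey]:
    """Build the individual's key, or None when any IR value is missing.

    Never returns a partial key.  A multi-valued IR property raises
    :class:`AmbiguousIdentityError`: keys must be univocal, and silently
    picking one value would hide a data problem.
    """
    items = []
    onto = kb.ontology
    for prop in rule.identity_properties:
        if prop in onto.datatype_properties:
            vals = sorted({lex for p, lex, _ in individual.data_assertions
                           if p == prop})
        else:
            vals = sorted({kb.representative(obj)
                           for p, obj in individual.object_assertions
                           if p == prop})
        if not vals:
            return None
        if len(vals) > 1:
            raise AmbiguousIdentityError(
                f"identity property {prop} is multi-valued on "
                f"{individual.uri} ({vals})")
        items.append((prop, vals[0]))
    return IdentityKey(rule.target_class, tuple(items))


def resolve_identity(candidate: Individual, kb: KnowledgeBase,
                     rule: IdentityRule) -> tuple[str, Optional[str]]:
    """Decide the fate of a candidate not yet in the KB.

    Returns one of ``("unique", None)``, ``("merge", existing_uri)``,
    ``("link", existing_uri)``, ``("reject-incomplete", None)``.
    """
    key = identity_key(candidate, rule, kb)
    if key is None:
        return ("reject-incomplete", None)
    for uri, existing in kb.individuals.items():
        if not applies_to(existing, rule, kb):
            continue
        try:
            other = identity_key(existing, rule, kb)
        except AmbiguousIdentityError:
            continue
        if other is not None and other == key:
            return (rule.behaviour, uri)
    return ("unique", None)


def rewrite_references(kb: KnowledgeBase, old: str, new: str) -> None:
    """Repoint every object assertion and link from ``old`` to ``new``."""
    for ind in kb.individuals.values():
        rewritten = []
        for prop, obj in ind.object_assertions:
            target = new if obj == old else obj
            if (prop, target) not in rewritten:
                rewritten.append((prop, target))
        ind.object_assertions = rewritten
    for attr in ("same_as", "different_from"):
        pairs = []
        for pair in getattr(kb, attr):
            mapped = frozenset(new if u == old else u for u in pair)
            if len(mapped) == 2 and mapped not in pairs:
                pairs.append(mapped)
        setattr(kb, attr, pairs)


def merge_individuals(kb: KnowledgeBase, survivor_uri: str,
                      duplicate: Individual, rule: IdentityRule
                      ) -> tuple[str, Optional[str]]:
    """Merge a duplicate candidate into the surviving KB individual.

    Returns ``("merged", final_uri)`` on success.  The merge is aborted —
    ``("conflict", None)`` — when the union would put conflicting values on
    an identity property, and ``("inconsistent", None)`` when the merged
    result fails the structural consistency check; in both cases the KB is
    left unchanged and the caller decides what to do with the duplicate.
    """
    survivor = kb.individuals[survivor_uri]
    # conflicting identity-property values abort the merge
    for prop in rule.identity_properties:
        if prop in kb.ontology.datatype_properties:
            merged_vals = {lex for p, lex, _ in
                           survivor.data_assertions + duplicate.data_assertions
                           if p == prop}
        else:
            merged_vals = {kb.representative(o) for p, o in
                           survivor.object_assertions
                           + duplicate.object_assertions
                           if p == prop}
        if len(merged_vals) > 1:
            return ("conflict", None)
    trial = AxiomBatch()
    for expr in duplicate.asserted_classes:
        trial.assertions.append(("class", survivor_uri, expr))
    for prop, lex, dt in duplicate.data_assertions:
        trial.assertions.append(("data", survivor_uri, prop, lex, dt))
    for prop, obj in duplicate.object_assertions:
        trial.assertions.append(("object", survivor_uri, prop, obj))
    if not check_consistency(kb, trial).empty:
        return ("inconsistent", None)
    for expr in duplicate.asserted_classes:
        survivor.add_class(expr)
    for t in duplicate.data_assertions:
        survivor.add_data(*t)
    for t in duplicate.object_assertions:
        survivor.add_object(*t)
    for t in duplicate.provenance:
        survivor.add_provenance(*t)
    final_uri = survivor_uri
    if rule.merged_uri_policy == "fresh-prefix":
        key = identity_key(survivor, rule, kb)
        token = key.digest() if key is not None else survivor.token
        new_uri = (rule.fresh_prefix + local_name(rule.target_class) + "/" +
                   urllib.parse.quote(token, safe=""))
        if new_uri != survivor_uri:
            survivor.uri = new_uri
            kb.individuals[new_uri] = survivor
            del kb.individuals[survivor_uri]
            rewrite_references(kb, survivor_uri, new_uri)
            final_uri = new_uri
    return ("merged", final_uri)


def link_individuals(kb: KnowledgeBase, a: str, b: str) -> KnowledgeBase:
    """Add an ``owl:sameAs`` pair; both individuals are retained.

    Linking an individual to itself is a no-op; a pair already declared
    ``owl:differentFrom`` is refused.
    """
    if a == b:
        return kb
    for uri in (a, b):
        if not kb.known_uri(uri):
            raise UnknownTermError(
                f"cannot link unknown URI {uri!r}; declare it external "
                "first")
    pair = frozenset((a, b))
    joined = kb._component(a) | kb._component(b)
    for df in kb.different_from:
        if df <= joined:
            raise OntoforgeError(
                f"refusing sameAs({a}, {b}): clashes with differentFrom "
                f"{sorted(df)}")
    if pair not in kb.same_as:
        kb.same_as.append(pair)
    return kb
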