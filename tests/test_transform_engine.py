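"""Integration-level tests of the full transformation pipeline."""

import random

import pytest

from ontoforge.errors import RefuseToRunError
from ontoforge.fixtures import (
    GENE_MAPPING,
    ProjectBundle,
    SyntheticSpec,
    gene_example,
    materialize,
    molecule_example,
    random_project,
    run_bundle,
    run_integration,
    synthetic_pair,
)
from ontoforge.identity_engine import identity_key
from ontoforge.mapping_rules import build_identity_rules
from ontoforge.ontology_kb import serialize_kb
from ontoforge.transform_engine import RunConfig, congruence_sweep, transform

GENE_URI = "http://example.org/orthdata/Gene/1"


class TestGeneWorkedExample:
    def test_gene_individual_assertion_counts(self, gene_result):
        gene = gene_result.kb.individuals[GENE_URI]
        assert gene.data_assertions == [
            ("http://purl.org/net/orth#Identifier", "pyc-1",
             "http://www.w3.org/2001/XMLSchema#string")]
        by_prop = {p.rsplit("#")[-1].rsplit("/")[-1]: o
                   for p, o in gene.object_assertions}
        assert set(by_prop) == {"encodes", "in_taxon", "contained_in"}

    def test_linked_individuals_carry_expected_classes(self, gene_result):
        kb = gene_result.kb
        gene = kb.individuals[GENE_URI]
        targets = {p.rsplit("#")[-1].rsplit("/")[-1]:
                   kb.individuals[o].named_classes()
                   for p, o in gene.object_assertions}
        assert targets["encodes"] == {"http://purl.org/net/orth#Protein"}
        assert targets["in_taxon"] == {
            "http://purl.obolibrary.org/obo/ncbitaxon#organisms"}
        assert targets["contained_in"] == {
            "http://semanticscience.org/resource/database"}

    def test_every_admitted_instance_is_congruent(self, gene_result):
        sweep = congruence_sweep(gene_result)
        assert sweep
        assert all(rep.congruent for _, _, rep in sweep)

    def test_final_kb_passes_consistency(self, gene_result):
        assert gene_result.final_report.empty

    def test_missing_species_rejects_gene_as_incomplete(self):
        xml = ('<species NCBITaxId="6239"><database name="UniProt">'
               '<gene id="1" geneId="pyc-1" protId="O17732"/>'
               "</database></species>")
        # drop the species individual by removing its entity rule, so the
        # pattern cannot supply in_taxon and the identity key is incomplete
        bundle = gene_example()
        bundle.mapping_doc = GENE_MAPPING.replace(
            '  - {id: species, source: species, target: "ncbi:organisms"}\n',
            "").replace('      "?taxon": {entity: species}\n', "")
        bundle.pattern_docs = {"gene_context": (
            "?gene: INDIVIDUAL\n?protein: INDIVIDUAL\nBEGIN\n"
            "ADD ?protein instanceOf Protein,\n"
            "ADD ?gene encodes ?protein\nEND;")}
        res = run_bundle(bundle)
        assert GENE_URI not in res.kb.individuals
        assert any(r["action"] == "reject-incomplete" and
                   r["entity"] == "gene" for r in res.log)


class TestExecutionOrder:
    def test_phase_order_matches_method_steps(self, gene_result):
        phases = [r["phase"] for r in gene_result.log]
        assert phases.index("entity-rules") < phases.index("identity")
        first_identity = phases.index("identity")
        assert all(p != "entity-rules" for p in phases[first_identity:])

    def test_empty_instance_stream_yields_empty_kb(self):
        bundle = gene_example(xml="<container/>")
        res = run_bundle(bundle)
        assert not res.kb.individuals
        actions = {r["action"] for r in res.log}
        assert actions <= {"start", "end"}

    def test_validation_failure_refuses_to_run(self, gene_mat):
        bad = gene_example()
        bad.mapping_doc = GENE_MAPPING.replace("orth:Gene", "orth:Nope")
        with pytest.raises(RefuseToRunError):
            run_bundle(bad)


class TestConditionalPartition:
    @pytest.mark.parametrize("flags", [[1, 0, 1, 0, 0], [0, 0], [1, 1, 1]])
    def test_partition_matches_brute_force_filter(self, flags):
        res = run_bundle(molecule_example(flags))
        expected_chiral = {f"M{i}" for i, f in enumerate(flags, 1)
                           if f == 1}     # brute-force oracle
        produced = {u.rsplit("/", 1)[1] for u in res.kb.individuals
                    if "/Molecule/" in u}
        assert produced == expected_chiral
        skipped = {r["local_id"] for r in res.log
                   if r["action"] == "skip-condition"}
        assert skipped == {f"M{i}" for i, f in enumerate(flags, 1)
                           if f != 1}


class TestConsistencyGate:
    @pytest.mark.parametrize("seed", range(6))
    def test_exactly_faulty_batches_discarded(self, seed):
        bundle = random_project(seed)
        res = run_bundle(bundle)
        discarded = {r["local_id"] for r in res.log
                     if r["action"] == "discard"}
        assert discarded == set(bundle.truth["faulty"])
        assert res.final_report.empty

    def test_discarded_batches_leave_no_trace_in_kb(self):
        bundle = random_project(2)
        res = run_bundle(bundle)
        kept = {u.rsplit("/", 1)[1] for u in res.kb.individuals}
        assert kept == set(bundle.truth["clean"])


class TestIntegration:
    def test_merge_mode_counts_match_union_dedup_oracle(
            self, synthetic_merge_run):
        res, (a, b), truth = synthetic_merge_run
        # brute-force oracle recomputed from the emitted bundles alone
        import csv, io
        accs = []
        for bundle in (a, b):
            for row in csv.DictReader(io.StringIO(bundle.data["protein"])):
                if row["accession"]:
                    accs.append(row["accession"])
        assert len(res.kb.individuals) == len(set(accs))
        assert len(res.kb.individuals) == truth["expected_merged_count"]

    def test_link_mode_preserves_per_source_counts(self,
                                                   synthetic_link_run):
        res, _, truth = synthetic_link_run
        a_count = sum(1 for u in res.kb.individuals.values()
                      if u.provenance[0][0] == "synthetic-A")
        b_count = sum(1 for u in res.kb.individuals.values()
                      if u.provenance[0][0] == "synthetic-B")
        assert (a_count, b_count) == (100, 100)
        assert len(res.kb.same_as) == truth["expected_sameas_pairs"]

    def test_cross_source_merge_unions_provenance(self,
                                                  synthetic_merge_run):
        res, _, truth = synthetic_merge_run
        multi = [i for i in res.kb.individuals.values()
                 if len({p[0] for p in i.provenance}) == 2]
        assert len(multi) >= len(truth["shared_accessions"])

    def test_incomplete_identity_rejection_and_pattern_recovery(self):
        spec = SyntheticSpec(seed=4, n_entities=30, duplicate_rate=0.1,
                             overlap=5, missing_identity_rate=0.3)
        a, b, truth = synthetic_pair(spec)
        res = run_integration([a, b])
        rejected = [r for r in res.log if r["action"] == "reject-incomplete"]
        assert len(rejected) == truth["expected_rejected"]
        assert sorted(r["local_id"] for r in rejected) == sorted(
            truth["a"]["missing"] + truth["b"]["missing"])
        a2, b2, _ = synthetic_pair(spec, include_recovery=True)
        res2 = run_integration([a2, b2])
        assert not [r for r in res2.log
                    if r["action"] == "reject-incomplete"]


class TestDeterminismAndOrderRobustness:
    def test_repeated_runs_byte_identical(self):
        docs = set()
        logs = set()
        for _ in range(2):
            res = run_bundle(gene_example(), profile="owl")
            docs.add(serialize_kb(res.kb, "turtle", "owl"))
            logs.add(res.log_lines())
        assert len(docs) == 1
        assert len(logs) == 1

    def test_permuted_rows_change_only_surviving_uris(self):
        spec = SyntheticSpec(seed=7, n_entities=25, duplicate_rate=0.3,
                             overlap=0)
        a, _, _ = synthetic_pair(spec)
        res1 = run_bundle(a)
        lines = a.data["protein"].strip().split("\n")
        shuffled = lines[1:]
        random.Random(11).shuffle(shuffled)
        a_perm = ProjectBundle(**vars(a))
        a_perm.data = {"protein": "\n".join([lines[0]] + shuffled) + "\n"}
        res2 = run_bundle(a_perm)
        assert len(res1.kb.individuals) == len(res2.kb.individuals)
        assert _keyed_canonical(res1) == _keyed_canonical(res2)


def _keyed_canonical(res):
    """Assertion multiset keyed by identity key instead of URI."""
    mat_rules = res.rules
    rule = build_identity_rules(mat_rules, res.kb.ontology)[0]
    keyed = set()
    key_of = {}
    for uri, ind in res.kb.individuals.items():
        k = identity_key(ind, rule, res.kb)
        key_of[uri] = k.items if k else uri
    for uri, ind in res.kb.individuals.items():
        subject = key_of[uri]
        for cls in sorted(ind.named_classes()):
            keyed.add((subject, "class", cls))
        for p, lex, dt in ind.data_assertions:
            keyed.add((subject, "data", p, lex, dt))
        for p, o in ind.object_assertions:
            keyed.add((subject, "object", p, key_of.get(o, o)))
    return keyed
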