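"""Locus registry, extra-copy admission and pseudogene filters."""

import pytest

from protlift.annot_io import AnnotationDB, FeatureRecord
from protlift.copy_resolver import (CopyDecision, DnaCopyCandidate,
                                    LocusRegistry, ProtCopyCandidate,
                                    admit_dna_copies, admit_prot_copies,
                                    assign_copy_ids)


def _ref_db(n_cds=4, cds_len=30):
    """One reference gene with one isoform of ``n_cds`` CDS segments."""
    db = AnnotationDB()
    db.add(FeatureRecord("g1", "gene", "r", 1, 1000, "+",
                         attributes={"gene_biotype": "protein_coding"}))
    db.add(FeatureRecord("t1", "transcript", "r", 1, 1000, "+",
                         parent_id="g1", source_type="mRNA"))
    pos = 1
    for i in range(n_cds):
        db.add(FeatureRecord(f"t1.c{i}", "CDS", "r", pos, pos + cds_len - 1,
                             "+", phase=0, parent_id="t1"))
        pos += cds_len + 50
    return db.finalize()


def test_copy_decision_invariant():
    with pytest.raises(ValueError):
        CopyDecision("x", "dna", True, ["overlap_excess"])


def test_dna_copy_above_threshold_no_overlap_is_accepted():
    reg = LocusRegistry()
    decs = admit_dna_copies(
        [DnaCopyCandidate("g1_1", "g1", "c", 100, 400, 0.97)], reg)
    assert decs[0].accepted and "g1_1" in reg.entries


def test_dna_copy_below_sc_threshold_is_rejected():
    reg = LocusRegistry()
    decs = admit_dna_copies(
        [DnaCopyCandidate("g1_1", "g1", "c", 100, 400, 0.90)], reg,
        sc_threshold=0.95)
    assert not decs[0].accepted
    assert decs[0].reasons == ["below_sc_threshold"]


def test_dna_copy_with_half_overlap_is_rejected():
    reg = LocusRegistry()
    reg.add("existing", "gX", "c", 100, 400)
    decs = admit_dna_copies(
        [DnaCopyCandidate("g1_1", "g1", "c", 250, 550, 0.99)], reg)
    assert decs[0].reasons == ["overlap_excess"]


def test_reference_whitelisted_overlap_is_allowed():
    ref = AnnotationDB()
    ref.add(FeatureRecord("gA", "gene", "r", 1, 500, "+"))
    ref.add(FeatureRecord("gB", "gene", "r", 400, 900, "+"))   # overlaps gA
    ref.finalize()
    reg = LocusRegistry(ref)
    reg.add("gA", "gA", "c", 100, 600)
    decs = admit_dna_copies(
        [DnaCopyCandidate("gB", "gB", "c", 500, 1000, 0.99)], reg)
    assert decs[0].accepted


def test_admission_processes_best_identity_first():
    # two mutually overlapping candidates: only the better one survives
    reg = LocusRegistry()
    decs = admit_dna_copies(
        [DnaCopyCandidate("lo", "g1", "c", 100, 400, 0.96),
         DnaCopyCandidate("hi", "g1", "c", 150, 450, 0.99)], reg)
    by_id = {d.candidate_id: d for d in decs}
    assert by_id["hi"].accepted and not by_id["lo"].accepted


def test_intronless_candidate_of_multiexon_gene_is_rejected():
    reg = LocusRegistry()
    decs = admit_prot_copies(
        [ProtCopyCandidate("t1_d1", "g1", "c", 100, 220, 1, 120)],
        reg, _ref_db(n_cds=4))
    assert decs[0].reasons == ["single_cds_mismatch"]


def test_coding_length_ratio_half_is_rejected():
    decs = admit_prot_copies(
        [ProtCopyCandidate("t1_d1", "g1", "c", 100, 160, 1, 60)],
        LocusRegistry(), _ref_db(n_cds=1, cds_len=120))
    assert decs[0].reasons == ["length_ratio_out_of_range"]


def test_single_cds_both_ratio_one_is_accepted_with_gene_parent():
    ref = _ref_db(n_cds=1, cds_len=120)
    reg = LocusRegistry()
    decs = admit_prot_copies(
        [ProtCopyCandidate("t1_d1", "g1", "c", 100, 219, 1, 120)], reg, ref)
    assert decs[0].accepted
    from protlift.copy_resolver import synthesize_gene_parent
    gene = synthesize_gene_parent(ref, "g1", "g1_1", "c", 100, 219, "+")
    assert gene.attributes["gene_biotype"] == "protein_coding"
    assert gene.source_type == "gene"


def test_assign_copy_ids_first_copy_keeps_reference_id():
    entries = LocusRegistry()
    entries.add("cand", "GENE", "c", 10, 90)
    idmap = assign_copy_ids([entries.entries["cand"]], taken_base_ids=set())
    assert idmap["cand"] == ("GENE", 0)


def test_assign_copy_ids_extras_numbered_by_genomic_order():
    reg = LocusRegistry()
    reg.add("a", "GENE", "chr2", 500, 600)
    reg.add("b", "GENE", "chr1", 100, 200)
    reg.add("c", "GENE", "chr1", 900, 990)
    idmap = assign_copy_ids(list(reg.entries.values()),
                            taken_base_ids={"GENE"})
    assert idmap["b"] == ("GENE_1", 1)      # chr1:100 first
    assert idmap["c"] == ("GENE_2", 2)
    assert idmap["a"] == ("GENE_3", 3)


def test_no_extras_leaves_ids_unchanged():
    assert assign_copy_ids([], set()) == {}


def test_accepted_loci_pairwise_overlap_respects_limit(default_run):
    """All-pairs sweep over the accepted loci of a full run."""
    reg_entries = [(g.seqid, g.start, g.end)
                   for g in default_run.out_db.genes()]
    for i, (s1, a1, b1) in enumerate(reg_entries):
        for s2, a2, b2 in reg_entries[i + 1:]:
            if s1 != s2:
                continue
            frac = LocusRegistry.overlap_fraction(a1, b1, a2, b2)
            assert frac <= 0.10 + 1e-9


def test_planted_pseudogene_rejected_and_duplicate_accepted(default_world,
                                                            default_run):
    got = {d.candidate_id: d for d in default_run.copy_decisions}
    for exp in default_world.expected_copies:
        d = got[exp.candidate_id]
        assert d.accepted == exp.accepted, exp.candidate_id
        if exp.reason:
            assert exp.reason in d.reasons
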