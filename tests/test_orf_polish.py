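"""Mutation classification, ORF search and CDS repair."""

import random

import pytest

from oracles import oracle_find_orfs
from protlift.annot_io import GenomeSequence
from protlift.orf_polish import (CATEGORIES, classify_mutations, find_orfs,
                                 orf_repair)
from protlift.seqtools import extract_spliced, translate


def _classify(ref_cds, tgt_cds, ref_tx=None, tgt_tx=None):
    return classify_mutations("t", ref_tx or ref_cds, tgt_tx or tgt_cds,
                              ref_cds, tgt_cds).categories


REF = "ATGAAACCCGGGTTTACATCTTAA"       # MKPGFTS*


@pytest.mark.parametrize("tgt, expected", [
    (REF, {"identical"}),
    (REF.replace("CCC", "CCA"), {"synonymous"}),                  # P->P
    (REF.replace("CCC", "GCC"), {"nonsynonymous"}),               # P->A
    (REF[:6] + "GCT" + REF[6:], {"inframe_insertion"}),
    (REF[:6] + REF[9:], {"inframe_deletion"}),
    (REF.replace("GGG", "TGA"), {"stop_gain"}),      # nonsense substitution
    (REF.replace("TAA", "CAA"), {"stop_loss"}),
    (REF.replace("ATGAAA", "CTGAAA"), {"start_loss"}),
], ids=["identical", "synonymous", "nonsynonymous", "inframe_insertion",
        "inframe_deletion", "stop_gain", "stop_loss", "start_loss"])
def test_classify_single_category_cases(tgt, expected):
    assert _classify(REF, tgt) == expected


def test_classify_frameshift_reads_through_old_stop():
    # a 1-nt deletion shifts the frame; the old terminal stop is no longer
    # read, so the frameshift co-occurs with a stop loss
    tgt = REF[:6] + REF[7:]
    assert _classify(REF, tgt) == {"frameshift", "stop_loss"}


def test_classify_frameshift_with_premature_stop():
    # the shifted frame hits TAG immediately after the deletion point
    ref = "ATGAAACTAGCCCGGTTTTAA"       # M K L A R F *
    tgt = ref[:6] + ref[7:]             # ...reads TAG in the new frame
    cats = _classify(ref, tgt)
    assert "frameshift" in cats and "stop_gain" in cats


def test_identical_requires_transcript_level_equality():
    # same CDS but a UTR substitution: not identical, protein intact
    cats = classify_mutations("t", "AAA" + REF, "AAC" + REF, REF, REF).categories
    assert cats == {"synonymous"}


def test_every_pair_gets_at_least_one_category():
    rnd = random.Random(23)
    for _ in range(100):
        n = rnd.randrange(9, 30, 3)
        ref = "ATG" + "".join(rnd.choice("ACGT") for _ in range(n)) + "TAA"
        tgt = list(ref)
        for _ in range(rnd.randint(0, 4)):
            tgt[rnd.randrange(len(tgt))] = rnd.choice("ACGT")
        cats = _classify(ref, "".join(tgt))
        assert cats and cats <= set(CATEGORIES)
        if "identical" in cats:
            assert cats == {"identical"}


@pytest.mark.parametrize("dna, expected", [
    ("ATGAAATAA", [(0, 0, 9, "MK")]),
    ("GATGAAATAA", [(1, 1, 10, "MK")]),
    ("ATGTAAATGAAAAAATAA", [(0, 6, 18, "MKK")]),   # longest in frame kept
])
def test_find_orfs_examples(dna, expected):
    got = [(o.frame, o.start_offset, o.end_offset, o.protein)
           for o in find_orfs(dna)]
    assert got == expected


def test_find_orfs_without_stop_extends_to_sequence_end():
    orfs = find_orfs("ATGAAACCC")
    assert orfs[0].has_stop is False
    assert orfs[0].protein == "MKP"


def test_find_orfs_no_atg_gives_empty_list():
    assert find_orfs("CCCGGGTTT") == []


def test_find_orfs_agrees_with_all_starts_scan():
    rnd = random.Random(7)
    for _ in range(120):
        dna = "".join(rnd.choice("ACGT") for _ in range(rnd.randint(3, 300)))
        got = {(o.frame, o.start_offset, o.end_offset, o.has_stop)
               for o in find_orfs(dna)}
        exp = {(f, s, e, stop)
               for f, (s, e, stop) in oracle_find_orfs(dna).items()}
        assert got == exp


def _repair_setup(genome_seq, cds_iv, report_cats, ref_protein):
    from protlift.orf_polish import MutationReport
    genome = GenomeSequence("c", genome_seq)
    spliced = extract_spliced(genome, [(1, len(genome_seq))], "+", "t")
    cds_dna = genome_seq[cds_iv[0] - 1:cds_iv[1]]
    report = MutationReport("t", set(report_cats))
    return orf_repair(spliced, [cds_iv], cds_dna, ref_protein, report)


def test_repair_switches_to_downstream_start_after_premature_stop():
    #            v premature stop         v true stop
    seq = "ATGTAAATGCCCAAACGCCTGAGCAAGCGCTAA"
    ref = "MHPKRLSKR"
    rep = _repair_setup(seq, (1, len(seq)), {"stop_gain"}, ref)
    assert rep.changed
    assert rep.cds_intervals[0][0] == 7          # the downstream ATG
    assert rep.protein.startswith("M") and "*" not in rep.protein
    assert rep.identity > 0.5


def test_repair_extends_cds_into_utr_after_stop_loss():
    # annotated CDS ends where the (mutated) stop used to be; the next
    # in-frame stop sits in the 3' UTR
    seq = "ATGAAACCCGGGCAA" + "ACCTCT" + "TAA" + "GCGC"
    ref = "MKPG"
    rep = _repair_setup(seq, (1, 15), {"stop_loss"}, ref)
    assert rep.changed
    assert rep.cds_intervals[-1][1] == 24        # through the UTR stop
    assert rep.orf.has_stop


def test_repair_leaves_annotation_when_no_orf_improves():
    seq = "ATGAAACCCGGGTTTACATCTTAA"
    ref = translate(seq)[:-1]
    rep = _repair_setup(seq, (1, len(seq)), {"frameshift"}, ref)
    assert not rep.changed
    assert rep.identity == 1.0


def test_repair_is_monotone_on_every_scenario(default_world, truth_by_tx,
                                              default_run):
    """Post-repair identity never drops below the chain-stage identity."""
    from protlift.identity import protein_identity
    for r in default_run.results:
        t = truth_by_tx.get(r.transcript_id)
        if t is None or not t.repairable:
            continue
        assert r.repaired
        assert protein_identity(t.truth_protein, r.protein) == 1.0
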