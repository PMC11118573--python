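"""Transcript pairing: overlap conditions, read-through removal, argmax."""

from protlift.annot_io import AnnotationDB, FeatureRecord, GenomeSequence
from protlift.pairing import match_transcripts, resolve_multicopy
from protlift.seqtools import revcomp


def _dna_db(genes):
    """genes: list of (gene_id, tx_id, start, end)"""
    db = AnnotationDB()
    for gid, tid, s, e in genes:
        db.add(FeatureRecord(gid, "gene", "c", s, e, "+"))
        db.add(FeatureRecord(tid, "transcript", "c", s, e, "+",
                             parent_id=gid, source_type="mRNA"))
    return db.finalize()


def _prot_db(txs):
    """txs: list of (tx_id, start, end) with a single CDS spanning the tx"""
    db = AnnotationDB()
    for tid, s, e in txs:
        db.add(FeatureRecord(tid, "transcript", "c", s, e, "+",
                             source_type="mRNA"))
        db.add(FeatureRecord(f"{tid}.c1", "CDS", "c", s, e, "+", phase=0,
                             parent_id=tid))
    return db.finalize()


def test_candidate_inside_matching_gene_is_paired():
    pairs = match_transcripts(_dna_db([("g1", "t1", 100, 500)]),
                              _prot_db([("t1", 150, 450)]))
    assert pairs["t1"].status == "both"
    assert pairs["t1"].prot_candidate_ids == ["t1"]


def test_candidate_overlapping_unrelated_gene_is_rejected():
    dna = _dna_db([("g1", "t1", 100, 500), ("g2", "t2", 600, 900)])
    pairs = match_transcripts(dna, _prot_db([("t1", 400, 700)]))
    # overlaps g2, which g1's locus does not overlap -> condition (2)
    assert pairs["t1"].status == "dna_only"


def test_overlap_shared_with_matched_locus_is_allowed():
    # g1 and g2 overlap each other; a candidate touching both is legal
    dna = _dna_db([("g1", "t1", 100, 500), ("g2", "t2", 450, 900)])
    pairs = match_transcripts(dna, _prot_db([("t1", 200, 480)]))
    assert pairs["t1"].status == "both"


def test_unmatched_statuses():
    dna = _dna_db([("g1", "t1", 100, 500)])
    pairs = match_transcripts(dna, _prot_db([("t9", 1000, 1200)]))
    assert pairs["t1"].status == "dna_only"
    assert pairs["t9"].status == "prot_only"


def _coding_world():
    """Target genome with the reference CDS at 101 and a mutated copy at 401."""
    cds = "ATGAAACCCGGGTTTACATCTTAA"
    mut = "ATGAAACCCGGGTTTAGATCTTAA"          # one nonsynonymous change
    seq = "T" * 100 + cds + "T" * 276 + mut + "T" * 76
    genome = {"c": GenomeSequence("c", seq)}
    ref_protein = "MKPGFTS"
    return genome, ref_protein, cds


def test_resolve_multicopy_picks_highest_identity():
    genome, refp, _ = _coding_world()
    dna = _dna_db([("g1", "t1", 50, 700)])
    prot = _prot_db([("t1", 401, 424), ("t1_ditto1", 101, 124)])
    pairs = match_transcripts(dna, prot)
    pair = resolve_multicopy(pairs["t1"], refp, genome, dna, prot)
    assert pair.chosen_prot_id == "t1_ditto1"       # the exact copy wins
    assert pair.candidate_identities["t1_ditto1"] == 1.0


def test_read_through_candidate_removed_despite_higher_identity():
    genome, refp, _ = _coding_world()
    # two distinct gene loci; a candidate spanning both is a read-through
    dna = _dna_db([("g1", "t1", 80, 200), ("g2", "t2", 380, 500)])
    prot = _prot_db([("t1", 101, 424), ("t1_ditto1", 401, 424)])
    pairs = match_transcripts(dna, prot)
    pair = pairs["t1"]
    pair.prot_candidate_ids = ["t1", "t1_ditto1"]   # force both through
    pair = resolve_multicopy(pair, refp, genome, dna, prot)
    assert "t1" not in pair.prot_candidate_ids
    assert pair.chosen_prot_id == "t1_ditto1"


def test_single_candidate_is_chosen():
    genome, refp, _ = _coding_world()
    dna = _dna_db([("g1", "t1", 50, 200)])
    prot = _prot_db([("t1", 101, 124)])
    pairs = match_transcripts(dna, prot)
    pair = resolve_multicopy(pairs["t1"], refp, genome, dna, prot)
    assert pair.chosen_prot_id == "t1"


def test_pairing_is_bijective_on_clean_worlds(default_world):
    """When every protein candidate sits inside its own gene's span, the
    matching is one-to-one."""
    pairs = match_transcripts(default_world.dna_db, default_world.prot_db)
    chosen = []
    for t in default_world.truth:
        pair = pairs[t.transcript_id]
        assert pair.dna_tx_id == t.transcript_id
        assert t.transcript_id in pair.prot_candidate_ids
        chosen.append(pair.dna_tx_id)
    assert len(set(chosen)) == len(chosen)


def test_no_pair_overlaps_unrelated_locus(default_world):
    dna = default_world.dna_db
    prot = default_world.prot_db
    pairs = match_transcripts(dna, prot)
    for pair in pairs.values():
        if pair.dna_tx_id is None:
            continue
        dna_gene = dna[dna[pair.dna_tx_id].parent_id]
        allowed = set(dna.genes_overlapping(dna_gene.seqid, dna_gene.start,
                                            dna_gene.end, dna_gene.strand))
        for cid in pair.prot_candidate_ids:
            c = prot[cid]
            hit = set(dna.genes_overlapping(c.seqid, c.start, c.end, c.strand))
            assert hit <= allowed
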