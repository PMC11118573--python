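"""CDS boundary mapping, group formation and chain selection."""

import pytest

from protlift.annot_io import FeatureRecord, GenomeSequence
from protlift.chaining import (candidate_protein, form_groups,
                               map_cds_boundaries, order_5p_to_3p,
                               reconcile_pair)
from protlift.identity import PairwiseAlignment, align_protein, protein_identity
from protlift.synthetic import ScenarioSpec, make_world


def _cds(fid, s, e):
    return FeatureRecord(fid, "CDS", "c", s, e, "+", phase=0)


def test_boundaries_of_gapless_alignment_follow_cds_lengths():
    # two 9-nt CDSs, query == reference protein of 6 residues
    aln = align_protein("MKVLLS", "MKVLLS")
    bmap = map_cds_boundaries(aln, [_cds("c1", 1, 9), _cds("c2", 10, 18)])
    assert [(b.ref_aa_start, b.ref_aa_end) for b in bmap.boundaries] == \
        [(0, 3), (3, 6)]


def test_query_insertion_shifts_reference_boundary():
    # query carries one extra residue inside CDS 1: the reference interval
    # of CDS 1 is one residue narrower than its nucleotide length suggests
    aln = PairwiseAlignment("MKV-LLS", "MKVALLS", 0)
    bmap = map_cds_boundaries(aln, [_cds("c1", 1, 12), _cds("c2", 13, 21)])
    assert bmap.boundaries[0].ref_aa_end == 3
    assert bmap.boundaries[1].ref_aa_end == 6


def test_mid_codon_boundary_counts_complete_codons_only():
    # CDS 1 ends mid-codon (7 nt): only 2 complete query codons before it
    aln = align_protein("MKVL", "MKVL")
    bmap = map_cds_boundaries(aln, [_cds("c1", 1, 7), _cds("c2", 8, 12)])
    assert bmap.boundaries[0].qry_aa_end == 2
    assert bmap.boundaries[0].ref_aa_end == 2


def test_form_groups_single_cds_each_yields_one_pair():
    aln = align_protein("MKVLLS", "MKVLLS")
    a = map_cds_boundaries(aln, [_cds("a1", 1, 18)])
    b = map_cds_boundaries(aln, [_cds("b1", 1, 18)])
    blocks = form_groups(a, b)
    assert len(blocks) == 1
    assert blocks[0][0].ref_span == (0, 6)


def test_form_groups_without_shared_interior_endpoint_spans_everything():
    aln = align_protein("MKVLLS", "MKVLLS")
    # 2 CDSs ending at aa 2|6 vs 3 CDSs ending at aa 1|4|6: no shared interior
    a = map_cds_boundaries(aln, [_cds("a1", 1, 6), _cds("a2", 7, 18)])
    b = map_cds_boundaries(aln, [_cds("b1", 1, 3), _cds("b2", 4, 12),
                                 _cds("b3", 13, 18)])
    blocks = form_groups(a, b)
    assert len(blocks) == 1
    assert len(blocks[0][0].cds_list) == 2 and len(blocks[0][1].cds_list) == 3


def test_form_groups_closes_at_shared_endpoints():
    aln = align_protein("MKVLLS", "MKVLLS")
    a = map_cds_boundaries(aln, [_cds("a1", 1, 9), _cds("a2", 10, 18)])
    b = map_cds_boundaries(aln, [_cds("b1", 1, 9), _cds("b2", 10, 18)])
    blocks = form_groups(a, b)
    assert [gl.ref_span for gl, _ in blocks] == [(0, 3), (3, 6)]


def _worked_example_selection(seed=1):
    world = make_world([ScenarioSpec("combined_errors", seed)])
    tx = world.truth[0].transcript_id
    genome = world.target_genome[world.dna_db[tx].seqid]
    dna = order_5p_to_3p(world.dna_db.cds_of(tx), "+")
    prot = order_5p_to_3p(world.prot_db.cds_of(tx), "+")
    return world, reconcile_pair(world.truth[0].ref_protein, genome, dna, prot, "+")


def test_worked_example_groups_match_expected_topology():
    _, sel = _worked_example_selection()
    shape = [(len(gl.cds_list), len(gm.cds_list)) for gl, gm in sel.blocks]
    assert shape == [(1, 1), (1, 1), (2, 2), (1, 1), (2, 1)]


def test_worked_example_chain_takes_protein_block_three():
    _, sel = _worked_example_selection()
    assert sel.winners == ["dna", "dna", "prot", "dna", "dna"]
    names = [c.feature_id.rsplit(".", 1)[-1] for c in sel.merged_cds]
    assert names == ["cds1", "cds2", "mpcds3", "mpcds4", "cds5", "cds6", "cds7"]
    assert sel.merged_protein_id == 1.0


def test_all_block_ties_keep_the_dna_candidate():
    world = make_world([ScenarioSpec("clean", 3)])
    tx = world.truth[0].transcript_id
    genome = world.target_genome[world.dna_db[tx].seqid]
    dna = order_5p_to_3p(world.dna_db.cds_of(tx), "+")
    prot = order_5p_to_3p(world.prot_db.cds_of(tx), "+")
    sel = reconcile_pair(world.truth[0].ref_protein, genome, dna, prot, "+")
    assert set(sel.winners) == {"dna"}
    assert [(c.start, c.end) for c in sel.merged_cds] == \
        [(c.start, c.end) for c in dna]


def test_block_with_premature_stop_goes_to_protein_source():
    world = make_world([ScenarioSpec("missed_splice_dna", 9)])
    tx = world.truth[0].transcript_id
    genome = world.target_genome[world.dna_db[tx].seqid]
    dna = order_5p_to_3p(world.dna_db.cds_of(tx), "+")
    prot = order_5p_to_3p(world.prot_db.cds_of(tx), "+")
    sel = reconcile_pair(world.truth[0].ref_protein, genome, dna, prot, "+")
    assert "prot" in sel.winners
    assert sel.merged_protein_id == 1.0


def test_merged_chain_never_reuses_a_cds_and_stays_ordered():
    for seed in (1, 2, 3):
        _, sel = _worked_example_selection(seed)
        ids = [c.feature_id for c in sel.merged_cds]
        assert len(ids) == len(set(ids))
        starts = [c.start for c in sel.merged_cds]
        assert starts == sorted(starts)


def test_chain_dominance_on_every_scenario(default_world):
    """Merged identity is never below the better of the two candidates."""
    w = default_world
    for t in w.truth:
        tx = t.transcript_id
        genome = w.target_genome[w.dna_db[tx].seqid]
        dna = order_5p_to_3p(w.dna_db.cds_of(tx), "+")
        prot = order_5p_to_3p(w.prot_db.cds_of(tx), "+")
        sel = reconcile_pair(t.ref_protein, genome, dna, prot, "+")
        ids = []
        for cds in (dna, prot):
            p, _ = candidate_protein(genome, cds, "+")
            ids.append(protein_identity(t.ref_protein, p) if p else 0.0)
        assert sel.merged_protein_id >= max(ids) - 1e-9


def test_missing_candidate_falls_back_to_the_other_source():
    world = make_world([ScenarioSpec("clean", 5)])
    tx = world.truth[0].transcript_id
    genome = world.target_genome[world.dna_db[tx].seqid]
    dna = order_5p_to_3p(world.dna_db.cds_of(tx), "+")
    sel = reconcile_pair(world.truth[0].ref_protein, genome, dna, [], "+")
    assert sel.winners == ["dna"] and sel.merged_protein_id == 1.0
    sel2 = reconcile_pair(world.truth[0].ref_protein, genome, [],
                          order_5p_to_3p(world.prot_db.cds_of(tx), "+"), "+")
    assert sel2.winners == ["prot"] and sel2.merged_protein_id == 1.0


def test_frame_continuity_at_junctions():
    """No stop codon appears at a source switch that neither source has."""
    from protlift.seqtools import translate
    from protlift.chaining import candidate_protein
    for seed in (1, 4, 8):
        world, sel = _worked_example_selection(seed)
        prot = sel.merged_protein
        assert "*" not in prot
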