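"""FASTA/GFF3 I/O, the feature store, and reference preprocessing."""

import pytest

from protlift import annot_io
from protlift.annot_io import AnnotationDB, FeatureRecord

TOY_GFF = """##gff-version 3
chr1\t.\tgene\t100\t400\t.\t+\t.\tID=g1;gene_biotype=protein_coding
chr1\t.\tmRNA\t100\t400\t.\t+\t.\tID=t1;Parent=g1
chr1\t.\texon\t300\t400\t.\t+\t.\tID=t1.e2;Parent=t1
chr1\t.\texon\t100\t200\t.\t+\t.\tID=t1.e1;Parent=t1
chr1\t.\tCDS\t150\t200\t.\t+\t0\tID=t1.c1;Parent=t1
chr1\t.\tCDS\t300\t350\t.\t+\t1\tID=t1.c2;Parent=t1
"""

MINIPROT_GFF = """##gff-version 3
chr1\t.\tmRNA\t100\t400\t.\t+\t.\tID=t1
chr1\t.\tCDS\t100\t200\t.\t+\t0\tID=t1.c1;Parent=t1
chr1\t.\tCDS\t300\t400\t.\t+\t1\tID=t1.c2;Parent=t1
"""

TOY_GTF = (
    'chr1\t.\tgene\t1\t300\t.\t+\t.\tgene_id "g1"; gene_biotype "protein_coding";\n'
    'chr1\t.\ttranscript\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\t.\texon\t1\t300\t.\t+\t.\tgene_id "g1"; transcript_id "t1";\n'
    'chr1\t.\tCDS\t1\t300\t.\t+\t0\tgene_id "g1"; transcript_id "t1";\n'
)


@pytest.mark.parametrize("fasta, expected", [
    (">s1\nacgt\n", {"s1": "ACGT"}),
    (">s1\nACGU\n", {"s1": "ACGT"}),
    (">a\nAC\n>b\nGT\n", {"a": "AC", "b": "GT"}),
])
def test_read_fasta_normalizes(tmp_path, fasta, expected):
    p = tmp_path / "g.fa"
    p.write_text(fasta)
    genomes = annot_io.read_fasta(str(p))
    assert {k: v.sequence for k, v in genomes.items()} == expected
    assert list(genomes) == list(expected)      # record order preserved


def test_read_fasta_replaces_odd_characters_with_n(tmp_path):
    p = tmp_path / "g.fa"
    p.write_text(">s\nACRGT\n")
    assert annot_io.read_fasta(str(p))["s"].sequence == "ACNGT"


def test_read_fasta_rejects_duplicates_and_empty(tmp_path):
    dup = tmp_path / "dup.fa"
    dup.write_text(">a\nAC\n>a\nGT\n")
    with pytest.raises(ValueError, match="duplicate"):
        annot_io.read_fasta(str(dup))
    empty = tmp_path / "empty.fa"
    empty.write_text("")
    with pytest.raises(ValueError):
        annot_io.read_fasta(str(empty))


def test_read_annotation_builds_sorted_hierarchy(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(TOY_GFF)
    db = annot_io.read_annotation(str(p))
    assert len(db) == 6
    assert not db.parentless
    kids = db.children_of("t1")
    assert [k.start for k in kids] == sorted(k.start for k in kids)
    assert [c.feature_id for c in db.cds_of("t1")] == ["t1.c1", "t1.c2"]
    assert db["g1"].attributes["gene_biotype"] == "protein_coding"


def test_read_annotation_flags_parentless_protein_files(tmp_path):
    p = tmp_path / "mp.gff3"
    p.write_text(MINIPROT_GFF)
    db = annot_io.read_annotation(str(p))
    assert db.parentless
    assert [c.phase for c in db.cds_of("t1")] == [0, 1]


def test_read_gtf_preserves_biotype(tmp_path):
    p = tmp_path / "a.gtf"
    p.write_text(TOY_GTF)
    db = annot_io.read_annotation(str(p), dialect="gtf")
    genes = db.genes()
    assert len(genes) == 1
    assert annot_io.gene_biotype(genes[0]) == "protein_coding"
    assert db.cds_of("t1")


def test_dangling_parent_is_an_error(tmp_path):
    p = tmp_path / "bad.gff3"
    p.write_text("##gff-version 3\n"
                 "chr1\t.\tmRNA\t1\t10\t.\t+\t.\tID=t1;Parent=missing\n")
    with pytest.raises(ValueError, match="missing"):
        annot_io.read_annotation(str(p))


def _roundtrip(db, tmp_path, name="rt.gff3"):
    out = tmp_path / name
    annot_io.write_gff3(db, str(out))
    return annot_io.read_annotation(str(out))


def test_write_gff3_roundtrip_is_fixed_point(tmp_path):
    p = tmp_path / "a.gff3"
    p.write_text(TOY_GFF)
    db1 = annot_io.read_annotation(str(p))
    db2 = _roundtrip(db1, tmp_path)
    db3 = _roundtrip(db2, tmp_path, "rt2.gff3")
    for da, dbb in ((db1, db2), (db2, db3)):
        assert set(da.features) == set(dbb.features)
        for fid in da.features:
            a, b = da[fid], dbb[fid]
            assert (a.seqid, a.start, a.end, a.strand, a.phase,
                    a.source_type, a.parent_id) == \
                   (b.seqid, b.start, b.end, b.strand, b.phase,
                    b.source_type, b.parent_id)
            assert a.attributes == b.attributes


def test_extra_copy_attributes_survive_reparse(tmp_path):
    db = AnnotationDB()
    db.add(FeatureRecord("g1_1", "gene", "chr1", 10, 90, "+",
                         attributes={"extra_copy_number": "1",
                                     "protein_identity": "0.9871"}))
    db.finalize()
    db2 = _roundtrip(db, tmp_path)
    assert db2["g1_1"].attributes["extra_copy_number"] == "1"
    assert db2["g1_1"].attributes["protein_identity"] == "0.9871"


def test_empty_db_writes_header_only(tmp_path):
    out = tmp_path / "empty.gff3"
    annot_io.write_gff3(AnnotationDB(), str(out))
    assert out.read_text() == "##gff-version 3\n"


def _three_gene_db():
    db = AnnotationDB()
    for gid, seqid, bt in (("g1", "chr1", "protein_coding"),
                           ("g2", "chr1_alt", "protein_coding"),
                           ("g3", "chr1", "rRNA")):
        db.add(FeatureRecord(gid, "gene", seqid, 10, 100, "+",
                             attributes={"gene_biotype": bt}))
        db.add(FeatureRecord(f"{gid}.t", "transcript", seqid, 10, 100, "+",
                             parent_id=gid, source_type="mRNA"))
    return db.finalize()


def test_filter_reference_drops_scaffolds_and_biotypes():
    db = _three_gene_db()
    out = annot_io.filter_reference(db, ["_fix", "_alt"], ["rRNA"])
    assert {g.feature_id for g in out.genes()} == {"g1"}
    assert "g2.t" not in out.features and "g3.t" not in out.features


def test_filter_reference_with_empty_lists_is_identity():
    db = _three_gene_db()
    out = annot_io.filter_reference(db, [], [])
    assert set(out.features) == set(db.features)


def test_locus_index_matches_brute_force():
    db = AnnotationDB()
    import random
    rnd = random.Random(3)
    spans = {}
    for i in range(40):
        s = rnd.randint(1, 950)
        e = s + rnd.randint(5, 60)
        gid = f"g{i}"
        spans[gid] = (s, e)
        db.add(FeatureRecord(gid, "gene", "c", s, e, "+"))
    db.finalize()
    for _ in range(100):
        qs = rnd.randint(1, 950)
        qe = qs + rnd.randint(0, 80)
        expected = sorted(g for g, (s, e) in spans.items()
                          if s <= qe and e >= qs)
        assert sorted(db.genes_overlapping("c", qs, qe)) == expected
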