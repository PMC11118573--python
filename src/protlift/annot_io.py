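"""Reading and writing of FASTA and GFF3/GTF annotation, and the indexed feature store.

The in-memory :class:`AnnotationDB` holds a gene -> transcript -> exon/CDS
hierarchy with an interval index over gene spans, the shape shared by
reference annotations, DNA-alignment-based candidate annotations (gene
hierarchies with UTRs) and protein-alignment-based candidates (bare
mRNA -> CDS trees).  Parsing of GFF3/GTF goes through gffutils; the writer
and the reference preprocessing filters are local.
"""

from __future__ import annotations

import logging
import os
import tempfile
from dataclasses import dataclass, field, replace

import gffutils
from Bio import SeqIO
from intervaltree import IntervalTree

log = logging.getLogger(__name__)

_DNA_OK = set("ACGTN")

#: GFF feature types canonicalized to the internal ``gene`` type.
GENE_TYPES = {"gene", "pseudogene"}

#: GFF feature types canonicalized to the internal ``transcript`` type.
TRANSCRIPT_TYPES = {
    "mRNA", "transcript", "lnc_RNA", "lncRNA", "ncRNA", "miRNA", "snoRNA",
    "tRNA", "rRNA", "snRNA", "misc_RNA", "antisense_RNA", "V_gene_segment",
    "J_gene_segment", "C_gene_segment", "primary_transcript",
}


@dataclass
class GenomeSequence:
    """One contig/chromosome: uppercase DNA over {A,C,G,T,N}."""

    seqid: str
    sequence: str

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class FeatureRecord:
    """One GFF3 row. Coordinates are 1-based inclusive, GFF3 native."""

    feature_id: str
    ftype: str              # canonical: gene | transcript | exon | CDS | other
    seqid: str
    start: int
    end: int
    strand: str             # '+' or '-'
    phase: int | None = None
    attributes: dict = field(default_factory=dict)
    parent_id: str | None = None
    source: str = "."
    score: str = "."
    source_type: str | None = None   # original column-3 type, kept for round-trips

    def __post_init__(self):
        if self.start > self.end:
            raise ValueError(
                f"feature {self.feature_id}: start {self.start} > end {self.end}")
        if self.source_type is None:
            self.source_type = self.ftype

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def copy(self, **changes) -> "FeatureRecord":
        if "attributes" not in changes:
            changes["attributes"] = dict(self.attributes)
        return replace(self, **changes)


def canonical_type(gff_type: str) -> str:
    if gff_type in GENE_TYPES:
        return "gene"
    if gff_type in TRANSCRIPT_TYPES:
        return "transcript"
    if gff_type in ("exon", "CDS"):
        return gff_type
    return "other"


class AnnotationDB:
    """Indexed store of :class:`FeatureRecord` with hierarchy and locus queries."""

    def __init__(self):
        self.features: dict[str, FeatureRecord] = {}
        self._children: dict[str, list[str]] = {}
        self._gene_tree: dict[str, IntervalTree] = {}
        self.parentless: bool = False   # set when transcripts arrive without gene parents

    # -- construction ---------------------------------------------------

    def add(self, rec: FeatureRecord) -> None:
        if rec.feature_id in self.features:
            raise ValueError(f"duplicate feature id {rec.feature_id!r}")
        self.features[rec.feature_id] = rec
        if rec.parent_id is not None:
            self._children.setdefault(rec.parent_id, []).append(rec.feature_id)
        if rec.ftype == "gene":
            self._gene_tree.setdefault(rec.seqid, IntervalTree()).addi(
                rec.start, rec.end + 1, rec.feature_id)

    def add_subtree(self, records: list[FeatureRecord]) -> None:
        for r in records:
            self.add(r)

    def finalize(self) -> "AnnotationDB":
        """Sort children by start and validate parent references."""
        dangling = [(fid, r.parent_id) for fid, r in self.features.items()
                    if r.parent_id is not None and r.parent_id not in self.features]
        if dangling:
            listing = ", ".join(f"{fid} -> {pid}" for fid, pid in sorted(dangling))
            raise ValueError(f"dangling Parent references: {listing}")
        for pid in self._children:
            self._children[pid].sort(key=lambda fid: (self.features[fid].start,
                                                      self.features[fid].end,
                                                      fid))
        top_tx = [r for r in self.features.values()
                  if r.ftype == "transcript" and r.parent_id is None]
        if top_tx:
            self.parentless = True
        return self

    # -- queries --------------------------------------------------------

    def __len__(self) -> int:
        return len(self.features)

    def __contains__(self, fid: str) -> bool:
        return fid in self.features

    def __getitem__(self, fid: str) -> FeatureRecord:
        return self.features[fid]

    def get(self, fid: str) -> FeatureRecord | None:
        return self.features.get(fid)

    def children_of(self, fid: str) -> list[FeatureRecord]:
        return [self.features[c] for c in self._children.get(fid, [])]

    def top_level(self) -> list[FeatureRecord]:
        return [r for r in self.features.values() if r.parent_id is None]

    def genes(self) -> list[FeatureRecord]:
        return [r for r in self.features.values() if r.ftype == "gene"]

    def transcripts(self) -> list[FeatureRecord]:
        return [r for r in self.features.values() if r.ftype == "transcript"]

    def transcripts_of(self, gene_id: str) -> list[FeatureRecord]:
        return [c for c in self.children_of(gene_id) if c.ftype == "transcript"]

    def cds_of(self, tx_id: str) -> list[FeatureRecord]:
        return [c for c in self.children_of(tx_id) if c.ftype == "CDS"]

    def exons_of(self, tx_id: str) -> list[FeatureRecord]:
        return [c for c in self.children_of(tx_id) if c.ftype == "exon"]

    def subtree(self, fid: str) -> list[FeatureRecord]:
        out = [self.features[fid]]
        for c in self._children.get(fid, []):
            out.extend(self.subtree(c))
        return out

    def genes_overlapping(self, seqid: str, start: int, end: int,
                          strand: str | None = None) -> list[str]:
        """Gene ids whose [start, end] span intersects the query interval."""
        tree = self._gene_tree.get(seqid)
        if tree is None:
            return []
        hits = [iv.data for iv in tree.overlap(start, end + 1)]
        if strand is not None:
            hits = [g for g in hits if self.features[g].strand == strand]
        return sorted(hits, key=lambda g: (self.features[g].start, g))

    def remove_subtree(self, fid: str) -> None:
        for rec in self.subtree(fid):
            cid = rec.feature_id
            if rec.ftype == "gene":
                tree = self._gene_tree.get(rec.seqid)
                if tree is not None:
                    tree.removei(rec.start, rec.end + 1, cid)
            self._children.pop(cid, None)
            del self.features[cid]
        parent = None
        # fid already deleted; drop it from its parent's child list
        for pid, kids in self._children.items():
            if fid in kids:
                parent = pid
                break
        if parent is not None:
            self._children[parent].remove(fid)


# -- FASTA ---------------------------------------------------------------

def read_fasta(path: str) -> dict[str, GenomeSequence]:
    """Read a FASTA file into uppercase DNA, U->T, anything else -> N."""
    genomes: dict[str, GenomeSequence] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if rec.id in genomes:
            raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
        seq = str(rec.seq).upper().replace("U", "T")
        if not set(seq) <= _DNA_OK:
            bad = sorted(set(seq) - _DNA_OK)
            log.warning("sequence %s: characters %s replaced by N", rec.id, bad)
            seq = "".join(c if c in _DNA_OK else "N" for c in seq)
        if len(seq) == 0:
            raise ValueError(f"empty sequence for {rec.id!r} in {path}")
        genomes[rec.id] = GenomeSequence(rec.id, seq)
    if not genomes:
        raise ValueError(f"no FASTA records in {path}")
    return genomes


def write_fasta(genomes: dict[str, GenomeSequence], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes.values():
            fh.write(f">{g.seqid}\n")
            for i in range(0, len(g.sequence), width):
                fh.write(g.sequence[i:i + width] + "\n")


# -- GFF3 / GTF ----------------------------------------------------------

def read_annotation(path: str, dialect: str = "gff3") -> AnnotationDB:
    """Parse GFF3 or GTF into an :class:`AnnotationDB`.

    Protein-alignment-style files (bare mRNA -> CDS, no gene parents) are
    accepted; the resulting DB has ``parentless`` set.
    """
    if dialect not in ("gff3", "gtf"):
        raise ValueError(f"unknown dialect {dialect!r}")
    kwargs = {}
    if dialect == "gtf":
        # skip gffutils' gene/transcript inference when rows are explicit
        with open(path) as fh:
            types = {line.split("\t")[2] for line in fh
                     if line.strip() and not line.startswith("#")
                     and len(line.split("\t")) > 2}
        kwargs = {"disable_infer_genes": "gene" in types,
                  "disable_infer_transcripts": "transcript" in types}
    gdb = gffutils.create_db(
        path, ":memory:", force=True, keep_order=True,
        merge_strategy="create_unique", **kwargs,
    )
    db = AnnotationDB()
    for f in gdb.all_features():
        ctype = canonical_type(f.featuretype)
        if dialect == "gtf":
            parent = None
            if ctype == "transcript":
                parent = f.attributes.get("gene_id", [None])[0]
            elif ctype in ("exon", "CDS"):
                parent = f.attributes.get("transcript_id", [None])[0]
        else:
            parent = f.attributes.get("Parent", [None])[0]
        if parent == f.id:
            parent = None
        attrs = {k: ",".join(v) for k, v in f.attributes.items()
                 if k not in ("ID", "Parent")}
        phase = int(f.frame) if f.frame not in (None, ".", "") else None
        rec = FeatureRecord(
            feature_id=f.id, ftype=ctype, seqid=f.seqid,
            start=f.start, end=f.end,
            strand=f.strand if f.strand in ("+", "-") else "+",
            phase=phase, attributes=attrs, parent_id=parent,
            source=f.source or ".",
            score=str(f.score) if f.score not in (None, "") else ".",
            source_type=f.featuretype,
        )
        if rec.feature_id in db.features:
            continue  # gffutils emits inferred duplicates for GTF gene/transcript rows
        db.add(rec)
    return db.finalize()


def _fmt_attrs(rec: FeatureRecord) -> str:
    parts = [f"ID={rec.feature_id}"]
    if rec.parent_id is not None:
        parts.append(f"Parent={rec.parent_id}")
    for k, v in rec.attributes.items():
        parts.append(f"{k}={v}")
    return ";".join(parts)


def write_gff3(db: AnnotationDB, path: str) -> None:
    """Write GFF3, parents before children, top level sorted by position."""
    def emit(fh, rec: FeatureRecord):
        phase = "." if rec.phase is None else str(rec.phase)
        fh.write("\t".join([
            rec.seqid, rec.source, rec.source_type or rec.ftype,
            str(rec.start), str(rec.end), rec.score, rec.strand, phase,
            _fmt_attrs(rec),
        ]) + "\n")
        for child in db.children_of(rec.feature_id):
            emit(fh, child)

    tops = sorted(db.top_level(),
                  key=lambda r: (r.seqid, r.start, r.end, r.feature_id))
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for rec in tops:
            emit(fh, rec)


def gff3_string(db: AnnotationDB) -> str:
    with tempfile.NamedTemporaryFile("r", suffix=".gff3", delete=False) as tmp:
        name = tmp.name
    try:
        write_gff3(db, name)
        with open(name) as fh:
            return fh.read()
    finally:
        os.unlink(name)


# -- reference preprocessing --------------------------------------------

def gene_biotype(rec: FeatureRecord) -> str | None:
    """Biotype from NCBI-style ``gene_biotype`` or Ensembl-style ``gene_type``."""
    return rec.attributes.get("gene_biotype") or rec.attributes.get("gene_type")


def filter_reference(db: AnnotationDB,
                     drop_scaffold_suffixes: list[str] | None = None,
                     drop_biotypes: list[str] | None = None) -> AnnotationDB:
    """Drop genes on excluded scaffolds and genes of excluded biotypes.

    Emulates the reference preprocessing used for human lift-overs: patch
    and alternative scaffolds (seqids ending in e.g. ``_fix``/``_alt``) and
    high-copy biotypes such as rRNA are removed with all their descendants.
    """
    suffixes = tuple(drop_scaffold_suffixes or [])
    biotypes = set(drop_biotypes or [])
    out = AnnotationDB()
    for top in db.top_level():
        if suffixes and top.seqid.endswith(suffixes):
            continue
        if biotypes:
            bt = gene_biotype(top)
            if bt in biotypes:
                continue
        for rec in db.subtree(top.feature_id):
            out.add(rec.copy())
    return out.finalize()
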