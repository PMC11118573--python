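"""Self-contained synthetic test worlds.

Each world is a toy reference genome + annotation, a target genome carrying
planted mutations, and the two candidate target annotations: a DNA-based
(Liftoff-style) gene hierarchy with UTRs, and a protein-based
(miniprot-style) mRNA->CDS annotation. Candidate corruption is applied to
annotation *coordinates* — emulating the characteristic failure modes of
the two aligner families (missed splice junctions, retained introns,
skipped exons, pseudogene hits) — while genome mutations (indels, premature
stops, start/stop losses) are written into the target sequence itself. A
truth table records, per transcript, the expected mutation categories, the
expected per-block chaining winners, and the protein the final annotation
should encode.

Scenario catalogue:

======================  =======================================================
clean                   both candidates perfect; expect "identical"
inframe_indel           3-nt insertion in a middle CDS exon (both candidates)
frameshift_early_stop   1-nt deletion creating an immediate premature stop
downstream_start        point mutation to a premature stop; rescue ATG planted
                        a couple of codons downstream
stop_loss               terminal stop mutated away; in-frame stop planted in
                        the 3' UTR
start_loss_downstream   start codon mutated to a stop; rescue ATG downstream
start_loss_upstream     start codon deleted; in-frame rescue ATG planted in
                        the 5' UTR
missed_splice_dna       DNA candidate's acceptor site slides +6 nt (in frame)
missed_splice_prot      protein candidate retains an in-frame intron
skipped_exon_prot       protein candidate omits one coding exon
tandem_duplicate        near-identical second gene copy in the target; both
                        candidates report it; expect acceptance
processed_pseudogene    intronless retrocopy of a multi-exon gene; protein
                        candidate maps it; expect single-CDS rejection
partial_prot_copy       half-length retrocopy of a single-CDS gene; expect
                        coding-length-ratio rejection
combined_errors              seven-exon gene where the DNA candidate has a bad
                        junction between CDS 3 and 4 (frame-neutral, with a
                        premature stop) and the protein candidate fuses CDS
                        6 and 7 across an intron — the worked chaining
                        example with groups {L3,L4}/{M3,M4} and {L6,L7}/{M6}
======================  =======================================================
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass, field

import numpy as np

from .annot_io import (AnnotationDB, FeatureRecord, GenomeSequence,
                       write_fasta, write_gff3)
from .seqtools import translate

SCENARIOS = (
    "clean", "inframe_indel", "frameshift_early_stop", "downstream_start",
    "stop_loss", "start_loss_downstream", "start_loss_upstream",
    "missed_splice_dna", "missed_splice_prot", "skipped_exon_prot",
    "tandem_duplicate", "processed_pseudogene", "partial_prot_copy",
    "combined_errors",
)

_BASES = "ACGT"
_STOPS = {"TAA", "TAG", "TGA"}
_ALL_CODONS = [a + b + c for a in _BASES for b in _BASES for c in _BASES]
#: codons usable as neutral filler: never a stop, never a start
SAFE_CODONS = sorted(set(_ALL_CODONS) - _STOPS - {"ATG"})


@dataclass
class GeneShape:
    n_exons: int = 4
    codons_per_exon: tuple[int, int] = (12, 20)
    intron_len: tuple[int, int] = (45, 90)      # rounded up to a multiple of 3
    utr5_len: int = 24                          # multiple of 3, >= 15
    utr3_len: int = 24                          # multiple of 3, >= 15
    pad: int = 150


@dataclass
class ScenarioSpec:
    scenario: str
    seed: int
    shape: GeneShape = field(default_factory=GeneShape)

    def __post_init__(self):
        if self.scenario not in SCENARIOS:
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if self.scenario == "combined_errors" and self.shape.n_exons != 7:
            self.shape = GeneShape(n_exons=7)
        if self.scenario == "partial_prot_copy" and self.shape.n_exons != 1:
            self.shape = GeneShape(n_exons=1, codons_per_exon=(40, 60))
        if self.scenario in ("missed_splice_dna", "missed_splice_prot",
                             "skipped_exon_prot") and self.shape.n_exons < 3:
            self.shape = GeneShape(n_exons=4)


@dataclass
class TruthRecord:
    transcript_id: str
    gene_id: str
    scenario: str
    categories: frozenset
    winners: str                 # 'dna' | 'prot' | 'mixed'
    repairable: bool
    truth_protein: str
    ref_protein: str


@dataclass
class ExpectedCopy:
    candidate_id: str
    source: str                  # 'dna' | 'prot'
    accepted: bool
    reason: str | None = None


@dataclass
class World:
    ref_genome: dict[str, GenomeSequence]
    ref_db: AnnotationDB
    target_genome: dict[str, GenomeSequence]
    dna_db: AnnotationDB
    prot_db: AnnotationDB
    truth: list[TruthRecord]
    expected_copies: list[ExpectedCopy] = field(default_factory=list)

    def write(self, outdir: str) -> dict[str, str]:
        os.makedirs(outdir, exist_ok=True)
        paths = {
            "ref_fasta": os.path.join(outdir, "ref.fa"),
            "ref_gff": os.path.join(outdir, "ref.gff3"),
            "target_fasta": os.path.join(outdir, "target.fa"),
            "dna_gff": os.path.join(outdir, "dna_candidate.gff3"),
            "prot_gff": os.path.join(outdir, "prot_candidate.gff3"),
            "truth": os.path.join(outdir, "truth.tsv"),
        }
        write_fasta(self.ref_genome, paths["ref_fasta"])
        write_fasta(self.target_genome, paths["target_fasta"])
        write_gff3(self.ref_db, paths["ref_gff"])
        write_gff3(self.dna_db, paths["dna_gff"])
        write_gff3(self.prot_db, paths["prot_gff"])
        with open(paths["truth"], "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t")
            w.writerow(["transcript_id", "gene_id", "scenario", "categories",
                        "winners", "repairable", "truth_protein", "ref_protein"])
            for t in self.truth:
                w.writerow([t.transcript_id, t.gene_id, t.scenario,
                            ";".join(sorted(t.categories)), t.winners,
                            int(t.repairable), t.truth_protein, t.ref_protein])
        return paths


# -- sequence helpers ----------------------------------------------------

def _safe_codons(rng, n: int) -> list[str]:
    return [SAFE_CODONS[i] for i in rng.integers(0, len(SAFE_CODONS), n)]


def _random_dna(rng, n: int) -> str:
    return "".join(_BASES[i] for i in rng.integers(0, 4, n))


def _filler_no_atg(rng, n: int) -> str:
    s = _random_dna(rng, n)
    while "ATG" in s:
        s = s.replace("ATG", "ACG", 1)
    return s


def _scrub_offframe_starts(spliced: str, protected_codons: set[int]) -> str:
    """Remove every ATG that is not aligned to the codon grid of a spliced
    transcript (5' UTR + CDS + 3' UTR, with the UTR lengths multiples of 3).

    Off-frame start codons would seed spurious ORF candidates and make the
    scenario truth tables ambiguous (e.g. a chance off-frame ATG can recover
    the C-terminal half of a frameshifted protein). Mutated bases never turn
    an unprotected codon into a stop or a start; aligned codons listed in
    ``protected_codons`` are left untouched.
    """
    s = list(spliced)
    for _ in range(len(spliced)):
        seq = "".join(s)
        hit = next((i for i in range(len(seq) - 2)
                    if i % 3 != 0 and seq[i:i + 3] == "ATG"), None)
        if hit is None:
            break
        fixed = False
        for j in (hit + 1, hit, hit + 2):
            ci = j // 3
            if ci in protected_codons:
                continue
            for repl in "CGAT":
                if repl == s[j]:
                    continue
                cand = s[ci * 3:ci * 3 + 3]
                cand[j - ci * 3] = repl
                if "".join(cand) in ("TAA", "TAG", "TGA", "ATG"):
                    continue
                s[j] = repl
                fixed = True
                break
            if fixed:
                break
        if not fixed:        # fully protected overlap; cannot occur for the
            break            # planted codon vocabulary used here
    return "".join(s)


# -- coordinate edits ----------------------------------------------------

@dataclass
class Edit:
    """Replace ``ref_len`` bases starting at 1-based ``pos`` with ``alt``."""

    pos: int
    ref_len: int
    alt: str

    @property
    def delta(self) -> int:
        return len(self.alt) - self.ref_len


def apply_edits(seq: str, edits: list[Edit]) -> str:
    for e in sorted(edits, key=lambda e: e.pos, reverse=True):
        seq = seq[:e.pos - 1] + e.alt + seq[e.pos - 1 + e.ref_len:]
    return seq


def map_coord(pos: int, edits: list[Edit]) -> int:
    """Reference-contig position -> target-contig position. Positions inside
    a deleted region collapse onto the first surviving base after it."""
    delta = 0
    for e in sorted(edits, key=lambda e: e.pos):
        if pos >= e.pos + e.ref_len:
            delta += e.delta
        elif pos >= e.pos:
            off = pos - e.pos
            return e.pos + delta + min(off, len(e.alt))
    return pos + delta


def map_interval(iv: tuple[int, int], edits: list[Edit]) -> tuple[int, int]:
    s, e = map_coord(iv[0], edits), map_coord(iv[1], edits)
    return (s, e) if s <= e else (s, s)


# -- the gene model ------------------------------------------------------

@dataclass
class GeneModel:
    """A laid-out gene on its own reference contig (plus strand)."""

    contig: str
    gene_id: str
    tx_id: str
    seq: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]]
    coding: str                     # spliced CDS sequence (ATG ... stop)
    utr5: str
    utr3: str
    introns: list[str]
    exon_cds_codons: list[int]
    region: tuple[int, int]         # gene span (exon1 start .. last exon end)

    @property
    def cum_codons(self) -> list[int]:
        out, c = [], 0
        for n in self.exon_cds_codons:
            c += n
            out.append(c)
        return out

    def codon_pos(self, codon_idx: int) -> int:
        """1-based contig position of the first base of a coding codon."""
        off = codon_idx * 3
        for (s, e) in self.cds:
            seg = e - s + 1
            if off < seg:
                return s + off
            off -= seg
        raise ValueError(f"codon {codon_idx} beyond coding sequence")

    @property
    def ref_protein(self) -> str:
        p = translate(self.coding)
        return p[:-1] if p.endswith("*") else p


def _layout_gene(rng, spec: ScenarioSpec, contig: str, gene_id: str,
                 tx_id: str, codons: list[str], utr5: str, utr3: str,
                 introns: list[str], exon_codons: list[int]) -> GeneModel:
    shape = spec.shape
    coding = "".join(codons)
    pieces, exons, cds = [], [], []
    pos = 1
    pad5 = _random_dna(rng, shape.pad)
    pieces.append(pad5)
    pos += len(pad5)
    coff = 0
    for i, n_codons in enumerate(exon_codons):
        exon_start = pos
        if i == 0:
            pieces.append(utr5)
            pos += len(utr5)
        cds_start = pos
        cds_seq = coding[coff:coff + n_codons * 3]
        coff += n_codons * 3
        pieces.append(cds_seq)
        pos += len(cds_seq)
        cds.append((cds_start, pos - 1))
        if i == len(exon_codons) - 1:
            pieces.append(utr3)
            pos += len(utr3)
        exons.append((exon_start, pos - 1))
        if i < len(exon_codons) - 1:
            pieces.append(introns[i])
            pos += len(introns[i])
    region = (exons[0][0], exons[-1][1])
    pieces.append(_random_dna(rng, shape.pad))
    return GeneModel(contig, gene_id, tx_id, "".join(pieces), exons, cds,
                     coding, utr5, utr3, introns, exon_codons, region)


def _build_base_gene(rng, spec: ScenarioSpec, contig: str, gene_id: str,
                     tx_id: str) -> GeneModel:
    shape = spec.shape
    lo, hi = spec.shape.codons_per_exon
    exon_codons = [int(rng.integers(lo, hi + 1)) for _ in range(shape.n_exons)]
    if spec.scenario == "combined_errors":
        exon_codons = [max(n, 8) for n in exon_codons]
    n_total = sum(exon_codons)
    codons = ["ATG"] + _safe_codons(rng, n_total - 2) + ["TAA"]
    introns = []
    for _ in range(shape.n_exons - 1):
        n = int(rng.integers(*shape.intron_len))
        n += (-n) % 3
        introns.append(_random_dna(rng, n))
    utr5 = _filler_no_atg(rng, shape.utr5_len)
    # 3' UTR: three neutral codons, an in-frame stop, then ATG-free filler —
    # the planted stop is what a stop-loss repair is expected to find
    utr3 = ("".join(_safe_codons(rng, 3)) + "TAA"
            + _filler_no_atg(rng, shape.utr3_len - 12))
    return _layout_gene(rng, spec, contig, gene_id, tx_id, codons, utr5,
                        utr3, introns, exon_codons)


# -- scenario application ------------------------------------------------

@dataclass
class ScenarioOutcome:
    gene: GeneModel
    edits: list[Edit]
    dna_cds: list[tuple[int, int]]      # reference-contig coords
    dna_exons: list[tuple[int, int]]
    prot_cds: list[tuple[int, int]]
    truth: TruthRecord
    target_extra: str = ""              # appended after the edited contig
    extra_dna_gene: dict | None = None  # target-coord extra-copy subtree
    extra_prot_tx: dict | None = None
    expected_copies: list[ExpectedCopy] = field(default_factory=list)


def _mid_exon(gene: GeneModel) -> int:
    return len(gene.exon_cds_codons) // 2


def _rebuild_with(rng, spec, contig, gene_id, tx_id, mutate):
    """Build the base gene, then let ``mutate`` patch codons/UTRs before
    the final layout (so planted features land in the reference too)."""
    gene = _build_base_gene(rng, spec, contig, gene_id, tx_id)
    codons = [gene.coding[i:i + 3] for i in range(0, len(gene.coding), 3)]
    utr5, utr3 = gene.utr5, gene.utr3
    codons, utr5, utr3 = mutate(codons, utr5, utr3)
    full = utr5 + "".join(codons) + utr3
    protected = {ci for ci in range(len(full) // 3)
                 if full[ci * 3:ci * 3 + 3] in ("ATG", "TAA", "TAG", "TGA")}
    full = _scrub_offframe_starts(full, protected)
    n5, nc = len(utr5), len(codons) * 3
    utr5, utr3 = full[:n5], full[n5 + nc:]
    codons = [full[n5 + i:n5 + i + 3] for i in range(0, nc, 3)]
    return _layout_gene(rng, spec, contig, gene_id, tx_id, codons, utr5,
                        utr3, gene.introns, gene.exon_cds_codons)


def build_scenario(spec: ScenarioSpec, contig: str, gene_id: str,
                   tx_id: str) -> ScenarioOutcome:
    rng = np.random.default_rng(spec.seed)
    sc = spec.scenario
    lo = spec.shape.codons_per_exon[0] * spec.shape.n_exons
    if lo < 10:
        raise ValueError(
            f"infeasible gene shape for scenario {sc!r}: at least 10 codons "
            f"needed to plant mutations, shape guarantees only {lo}")
    ident = lambda c, u5, u3: (c, u5, u3)
    plant = ident

    if sc == "frameshift_early_stop":
        # the premature stop lands mid-protein: far enough in that the
        # truncated frame-0 reading beats any off-frame ORF by identity
        def plant(c, u5, u3):
            m = len(c) // 2
            c[m], c[m + 1] = "CTA", "AGG"
            return c, u5, u3
    elif sc == "downstream_start":
        def plant(c, u5, u3):
            c[2], c[4] = "CAA", "ATG"
            return c, u5, u3
    elif sc == "start_loss_downstream":
        def plant(c, u5, u3):
            c[3] = "ATG"
            return c, u5, u3
    elif sc == "start_loss_upstream":
        def plant(c, u5, u3):
            # in-frame rescue ATG twelve bases upstream of the start codon
            u5 = u5[:-12] + "ATG" + "".join(_safe_codons(rng, 3))
            return c, u5, u3

    gene = _rebuild_with(rng, spec, contig, gene_id, tx_id, plant)
    refp = gene.ref_protein
    n_aa = len(refp)
    edits: list[Edit] = []
    dna_cds = list(gene.cds)
    dna_exons = list(gene.exons)
    prot_cds = list(gene.cds)
    cats: frozenset = frozenset({"identical"})
    winners = "dna"
    repairable = False
    truth_protein = refp
    target_extra = ""
    extra_dna = None
    extra_prot = None
    exp_copies: list[ExpectedCopy] = []

    if sc == "inframe_indel":
        k = _mid_exon(gene)
        j = gene.cum_codons[k - 1] + 2 if k > 0 else 2
        edits = [Edit(gene.codon_pos(j), 0, "GCT")]
        cats = frozenset({"inframe_insertion"})
        truth_protein = refp[:j] + "A" + refp[j:]
    elif sc == "frameshift_early_stop":
        m = len(gene.coding) // 3 // 2
        edits = [Edit(gene.codon_pos(m), 1, "")]     # delete C of CTA -> TAA...
        cats = frozenset({"frameshift", "stop_gain"})
        repairable = True
        truth_protein = refp[:m]
    elif sc == "downstream_start":
        edits = [Edit(gene.codon_pos(2), 1, "T")]    # CAA -> TAA
        cats = frozenset({"stop_gain"})
        repairable = True
        truth_protein = refp[4:]
    elif sc == "stop_loss":
        edits = [Edit(gene.codon_pos(n_aa), 1, "C")]  # TAA -> CAA
        cats = frozenset({"stop_loss"})
        repairable = True
        truth_protein = refp + "Q" + translate(gene.utr3[:9])
    elif sc == "start_loss_downstream":
        edits = [Edit(gene.codon_pos(0), 3, "TAG")]
        cats = frozenset({"start_loss", "stop_gain"})
        repairable = True
        truth_protein = refp[3:]
    elif sc == "start_loss_upstream":
        edits = [Edit(gene.codon_pos(0), 3, "")]
        cats = frozenset({"start_loss", "inframe_deletion"})
        repairable = True
        truth_protein = "M" + translate(gene.utr5[-9:]) + refp[1:]
    elif sc == "missed_splice_dna":
        k = _mid_exon(gene)
        s, e = dna_cds[k]
        dna_cds[k] = (s + 6, e)
        xs, xe = dna_exons[k]
        dna_exons[k] = (xs + 6, xe)
        winners = "mixed"
    elif sc == "missed_splice_prot":
        k = _mid_exon(gene) - 1          # retain intron k (after exon k)
        k = max(k, 0)
        intron = gene.introns[k]
        mid = (len(intron) // 2) // 3 * 3
        gene.introns[k] = intron[:mid] + "TAA" + intron[mid + 3:]
        gene.seq = gene.seq[:gene.cds[k][1]] \
            + gene.seq[gene.cds[k][1]:].replace(intron, gene.introns[k], 1)
        merged = (prot_cds[k][0], prot_cds[k + 1][1])
        prot_cds = prot_cds[:k] + [merged] + prot_cds[k + 2:]
    elif sc == "skipped_exon_prot":
        k = _mid_exon(gene)
        prot_cds = prot_cds[:k] + prot_cds[k + 1:]
    elif sc == "combined_errors":
        # DNA: junction between CDS 3 and 4 slides +4 on both sides
        # (frame-neutral overall); the first intron bases read as a stop.
        i3 = gene.introns[2]
        gene.seq = gene.seq[:gene.cds[2][1]] \
            + gene.seq[gene.cds[2][1]:].replace(i3, "TAAC" + i3[4:], 1)
        gene.introns[2] = "TAAC" + i3[4:]
        s3, e3 = dna_cds[2]
        s4, e4 = dna_cds[3]
        dna_cds[2], dna_cds[3] = (s3, e3 + 4), (s4 + 4, e4)
        x3, x4 = dna_exons[2], dna_exons[3]
        dna_exons[2], dna_exons[3] = (x3[0], x3[1] + 4), (x4[0] + 4, x4[1])
        # protein candidate: CDS 6 and 7 fused across (in-frame) intron 6
        fused = (prot_cds[5][0], prot_cds[6][1])
        prot_cds = prot_cds[:5] + [fused]
        winners = "mixed"
    elif sc == "tandem_duplicate":
        rs, re_ = gene.region
        dup = list(gene.seq[rs - 1:re_])
        # a few substitutions confined to the UTRs: identity stays >= 0.95
        # at the transcript level and the protein is untouched
        utr_positions = (list(range(gene.exons[0][0], gene.cds[0][0]))
                         + list(range(gene.cds[-1][1] + 1, gene.exons[-1][1] + 1)))
        for p in rng.choice(utr_positions, size=6, replace=False):
            old = dup[p - rs]
            dup[p - rs] = {"A": "G", "G": "A", "C": "T", "T": "C"}[old]
        spacer, tail = _random_dna(rng, 200), _random_dna(rng, 100)
        target_extra = spacer + "".join(dup) + tail
        shift = len(gene.seq) + 200 + 1 - rs
        extra_dna = {
            "gene_id": f"{gene_id}_1", "tx_id": f"{tx_id}_1",
            "exons": [(s + shift, e + shift) for s, e in gene.exons],
            "cds": [(s + shift, e + shift) for s, e in gene.cds],
            "span": (rs + shift, re_ + shift),
        }
        extra_prot = {
            "tx_id": f"{tx_id}_ditto1",
            "cds": [(s + shift, e + shift) for s, e in gene.cds],
        }
        exp_copies = [ExpectedCopy(f"{gene_id}_1", "dna", True),
                      ExpectedCopy(f"{tx_id}_ditto1", "prot", False,
                                   "overlap_excess")]
    elif sc in ("processed_pseudogene", "partial_prot_copy"):
        frac = 1.0 if sc == "processed_pseudogene" else 0.5
        n_nt = int(len(gene.coding) * frac) // 3 * 3
        retro = gene.coding[:n_nt]
        spacer, tail = _random_dna(rng, 200), _random_dna(rng, 100)
        target_extra = spacer + retro + tail
        start = len(gene.seq) + 200 + 1
        extra_prot = {
            "tx_id": f"{tx_id}_ditto1",
            "cds": [(start, start + n_nt - 1)],
        }
        reason = ("single_cds_mismatch" if sc == "processed_pseudogene"
                  else "length_ratio_out_of_range")
        exp_copies = [ExpectedCopy(f"{tx_id}_ditto1", "prot", False, reason)]

    truth = TruthRecord(tx_id, gene_id, sc, cats, winners, repairable,
                        truth_protein, refp)
    return ScenarioOutcome(gene, edits, dna_cds, dna_exons, prot_cds, truth,
                           target_extra, extra_dna, extra_prot, exp_copies)


# -- world assembly ------------------------------------------------------

def _gene_subtree(gene_id: str, tx_id: str, seqid: str,
                  exons: list[tuple[int, int]], cds: list[tuple[int, int]],
                  strand: str = "+", biotype: str = "protein_coding",
                  tx_type: str = "mRNA", gene_attrs: dict | None = None,
                  tx_attrs: dict | None = None,
                  cds_prefix: str = "cds") -> list[FeatureRecord]:
    span = (min(s for s, _ in exons), max(e for _, e in exons)) if exons \
        else (min(s for s, _ in cds), max(e for _, e in cds))
    out = [FeatureRecord(gene_id, "gene", seqid, span[0], span[1], strand,
                         attributes={"gene_biotype": biotype,
                                     **(gene_attrs or {})},
                         source_type="gene"),
           FeatureRecord(tx_id, "transcript", seqid, span[0], span[1], strand,
                         attributes=dict(tx_attrs or {}), parent_id=gene_id,
                         source_type=tx_type)]
    for i, (s, e) in enumerate(sorted(exons), 1):
        out.append(FeatureRecord(f"{tx_id}.exon{i}", "exon", seqid, s, e,
                                 strand, parent_id=tx_id))
    cum = 0
    for i, (s, e) in enumerate(sorted(cds), 1):
        out.append(FeatureRecord(f"{tx_id}.{cds_prefix}{i}", "CDS", seqid, s,
                                 e, strand, phase=(3 - cum % 3) % 3,
                                 parent_id=tx_id))
        cum += e - s + 1
    return out


def _prot_subtree(tx_id: str, seqid: str, cds: list[tuple[int, int]],
                  strand: str = "+") -> list[FeatureRecord]:
    span = (min(s for s, _ in cds), max(e for _, e in cds))
    out = [FeatureRecord(tx_id, "transcript", seqid, span[0], span[1], strand,
                         source_type="mRNA")]
    cum = 0
    for i, (s, e) in enumerate(sorted(cds), 1):
        out.append(FeatureRecord(f"{tx_id}.mpcds{i}", "CDS", seqid, s, e,
                                 strand, phase=(3 - cum % 3) % 3,
                                 parent_id=tx_id))
        cum += e - s + 1
    return out


def _add_noncoding(rng, ref_genome, ref_db, target_genome, dna_db):
    """A lncRNA gene and a miRNA gene, lifted verbatim by the DNA candidate
    (protein-based mapping cannot see them)."""
    seq = _random_dna(rng, 900)
    g = GenomeSequence("chr_nc", seq)
    ref_genome["chr_nc"] = g
    target_genome["chr_nc"] = GenomeSequence("chr_nc", seq)
    lnc = _gene_subtree("G_lnc", "T_lnc", "chr_nc",
                        exons=[(101, 220), (301, 420)], cds=[],
                        biotype="lncRNA", tx_type="lnc_RNA")
    mir = _gene_subtree("G_mir", "T_mir", "chr_nc",
                        exons=[(601, 680)], cds=[],
                        biotype="miRNA", tx_type="miRNA")
    for rec in lnc + mir:
        ref_db.add(rec.copy())
        dna_db.add(rec.copy())


def make_world(specs: list[ScenarioSpec],
               include_noncoding: bool = False) -> World:
    """Generate a complete world for the given scenario specs.

    Each spec gets its own contig; outputs are deterministic functions of
    the specs (scenario + seed + shape).
    """
    if not specs:
        raise ValueError("specs must be non-empty")
    ref_genome: dict[str, GenomeSequence] = {}
    target_genome: dict[str, GenomeSequence] = {}
    ref_db, dna_db, prot_db = AnnotationDB(), AnnotationDB(), AnnotationDB()
    truth: list[TruthRecord] = []
    expected_copies: list[ExpectedCopy] = []

    for idx, spec in enumerate(specs):
        contig = f"chr_{spec.scenario}_{idx}"
        # dashes, not underscores: a trailing "_<number>" would collide with
        # the extra-copy id convention of DNA-based lift-over output
        gene_id, tx_id = f"G-{spec.scenario}-{idx}", f"T-{spec.scenario}-{idx}"
        out = build_scenario(spec, contig, gene_id, tx_id)
        gene = out.gene
        ref_genome[contig] = GenomeSequence(contig, gene.seq)
        target_seq = apply_edits(gene.seq, out.edits) + out.target_extra
        target_genome[contig] = GenomeSequence(contig, target_seq)

        ref_db.add_subtree(_gene_subtree(gene_id, tx_id, contig, gene.exons,
                                         gene.cds))
        dna_exons = [map_interval(iv, out.edits) for iv in out.dna_exons]
        dcds = [map_interval(iv, out.edits) for iv in out.dna_cds]
        dna_db.add_subtree(_gene_subtree(gene_id, tx_id, contig, dna_exons,
                                         dcds))
        pcds = [map_interval(iv, out.edits) for iv in out.prot_cds]
        prot_db.add_subtree(_prot_subtree(tx_id, contig, pcds))

        if out.extra_dna_gene is not None:
            x = out.extra_dna_gene
            dna_db.add_subtree(_gene_subtree(
                x["gene_id"], x["tx_id"], contig, x["exons"], x["cds"],
                gene_attrs={"extra_copy_number": "1"},
                tx_attrs={"extra_copy_number": "1"}))
        if out.extra_prot_tx is not None:
            x = out.extra_prot_tx
            prot_db.add_subtree(_prot_subtree(x["tx_id"], contig, x["cds"]))

        truth.append(out.truth)
        expected_copies.extend(out.expected_copies)

    rng = np.random.default_rng(sum(s.seed for s in specs) % (2 ** 31) + 7)
    if include_noncoding:
        _add_noncoding(rng, ref_genome, ref_db, target_genome, dna_db)

    world = World(ref_genome, ref_db.finalize(), target_genome,
                  dna_db.finalize(), prot_db.finalize(), truth,
                  expected_copies)
    _validate(world)
    return world


def default_specs(seed: int) -> list[ScenarioSpec]:
    """One spec per scenario, seeds derived from ``seed``."""
    return [ScenarioSpec(sc, seed * 1000 + i)
            for i, sc in enumerate(SCENARIOS)]


def _validate(world: World) -> None:
    """Self-consistency: every reference protein is a clean ORF and every
    truth protein is non-empty and stop-free."""
    for t in world.truth:
        if "*" in t.ref_protein or not t.ref_protein.startswith("M"):
            raise AssertionError(f"{t.transcript_id}: reference protein invalid")
        if not t.truth_protein or "*" in t.truth_protein:
            raise AssertionError(f"{t.transcript_id}: truth protein invalid")
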