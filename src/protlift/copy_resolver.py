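"""Gene-locus overlap resolution and extra-copy admission.

Accepted gene loci live in a per-contig interval registry. A new locus may
overlap an existing one by at most 10% (of the shorter span) unless the two
source genes already overlap in the reference annotation. DNA-based extra
copies must additionally meet the sequence-identity threshold (``-sc``
semantics, default 0.95). Protein-based candidates — which carry no UTRs
and are prone to landing on processed pseudogenes — face two stricter
filters: an intronless (single-CDS) candidate is only accepted when the
reference gene is also single-CDS, and the candidate's total coding length
must be 0.9-1.5x that of the reference gene's longest isoform.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .annot_io import AnnotationDB, FeatureRecord

log = logging.getLogger(__name__)

MAX_OVERLAP_FRACTION = 0.10
LENGTH_RATIO_BOUNDS = (0.9, 1.5)
DEFAULT_SC_THRESHOLD = 0.95


@dataclass
class LocusEntry:
    locus_id: str
    ref_gene_id: str
    seqid: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class CopyDecision:
    candidate_id: str
    source: str                     # 'dna' | 'prot'
    accepted: bool
    reasons: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.accepted != (not self.reasons):
            raise ValueError("accepted iff reasons is empty")


class LocusRegistry:
    """Interval registry of accepted gene loci with a reference-overlap
    whitelist (pairs of reference genes that already overlap)."""

    def __init__(self, ref_db: AnnotationDB | None = None):
        self._trees: dict[str, IntervalTree] = {}
        self.entries: dict[str, LocusEntry] = {}
        self.whitelist: set[frozenset] = set()
        if ref_db is not None:
            for g in ref_db.genes():
                for other in ref_db.genes_overlapping(g.seqid, g.start, g.end):
                    if other != g.feature_id:
                        self.whitelist.add(frozenset((g.feature_id, other)))

    def add(self, locus_id: str, ref_gene_id: str, seqid: str,
            start: int, end: int) -> None:
        e = LocusEntry(locus_id, ref_gene_id, seqid, start, end)
        self.entries[locus_id] = e
        self._trees.setdefault(seqid, IntervalTree()).addi(start, end + 1, locus_id)

    def overlapping(self, seqid: str, start: int, end: int) -> list[LocusEntry]:
        tree = self._trees.get(seqid)
        if tree is None:
            return []
        return sorted((self.entries[iv.data] for iv in tree.overlap(start, end + 1)),
                      key=lambda e: (e.start, e.locus_id))

    def whitelisted(self, ref_gene_a: str, ref_gene_b: str) -> bool:
        return frozenset((ref_gene_a, ref_gene_b)) in self.whitelist

    @staticmethod
    def overlap_fraction(a_start: int, a_end: int, b_start: int, b_end: int) -> float:
        shared = min(a_end, b_end) - max(a_start, b_start) + 1
        if shared <= 0:
            return 0.0
        return shared / min(a_end - a_start + 1, b_end - b_start + 1)

    def overlap_violation(self, ref_gene_id: str, seqid: str,
                          start: int, end: int,
                          max_overlap: float = MAX_OVERLAP_FRACTION) -> bool:
        for e in self.overlapping(seqid, start, end):
            frac = self.overlap_fraction(start, end, e.start, e.end)
            if frac > max_overlap and not self.whitelisted(ref_gene_id, e.ref_gene_id):
                return True
        return False


@dataclass
class DnaCopyCandidate:
    gene_id: str
    ref_gene_id: str
    seqid: str
    start: int
    end: int
    dna_identity: float


def admit_dna_copies(candidates: list[DnaCopyCandidate], registry: LocusRegistry,
                     sc_threshold: float = DEFAULT_SC_THRESHOLD,
                     max_overlap: float = MAX_OVERLAP_FRACTION,
                     ) -> list[CopyDecision]:
    """Admit DNA-based extra gene copies, best identity first.

    Acceptance requires identity >= the sequence-identity threshold and at
    most ``max_overlap`` overlap with every already-accepted locus (unless
    the overlap also exists between the source genes in the reference).
    Accepted candidates are registered immediately, so admission order
    (descending identity, then position) affects later overlap checks.
    """
    decisions = []
    ordered = sorted(candidates,
                     key=lambda c: (-c.dna_identity, c.seqid, c.start, c.gene_id))
    for cand in ordered:
        reasons = []
        if cand.dna_identity < sc_threshold:
            reasons.append("below_sc_threshold")
        if registry.overlap_violation(cand.ref_gene_id, cand.seqid,
                                      cand.start, cand.end, max_overlap):
            reasons.append("overlap_excess")
        decision = CopyDecision(cand.gene_id, "dna", not reasons, reasons)
        if decision.accepted:
            registry.add(cand.gene_id, cand.ref_gene_id, cand.seqid,
                         cand.start, cand.end)
        decisions.append(decision)
    return decisions


@dataclass
class ProtCopyCandidate:
    tx_id: str
    ref_gene_id: str
    seqid: str
    start: int
    end: int
    n_cds: int
    coding_length: int


def _ref_longest_isoform(ref_db: AnnotationDB, gene_id: str) -> tuple[int, int]:
    """(n_cds, summed CDS length) of the reference gene's longest isoform,
    'longest' by total coding length."""
    best = (0, 0)
    for tx in ref_db.transcripts_of(gene_id):
        cds = ref_db.cds_of(tx.feature_id)
        total = sum(c.length for c in cds)
        if total > best[1]:
            best = (len(cds), total)
    return best


def admit_prot_copies(candidates: list[ProtCopyCandidate], registry: LocusRegistry,
                      ref_db: AnnotationDB,
                      max_overlap: float = MAX_OVERLAP_FRACTION,
                      ratio_bounds: tuple[float, float] = LENGTH_RATIO_BOUNDS,
                      ) -> list[CopyDecision]:
    """Admit protein-based gene loci under the stricter pseudogene filters."""
    decisions = []
    ordered = sorted(candidates, key=lambda c: (c.seqid, c.start, c.tx_id))
    for cand in ordered:
        reasons = []
        ref_n_cds, ref_coding = _ref_longest_isoform(ref_db, cand.ref_gene_id)
        if cand.n_cds == 1 and ref_n_cds > 1:
            reasons.append("single_cds_mismatch")
        if ref_coding > 0:
            ratio = cand.coding_length / ref_coding
            if not ratio_bounds[0] <= ratio <= ratio_bounds[1]:
                reasons.append("length_ratio_out_of_range")
        if registry.overlap_violation(cand.ref_gene_id, cand.seqid,
                                      cand.start, cand.end, max_overlap):
            reasons.append("overlap_excess")
        decision = CopyDecision(cand.tx_id, "prot", not reasons, reasons)
        if decision.accepted:
            registry.add(cand.tx_id, cand.ref_gene_id, cand.seqid,
                         cand.start, cand.end)
        decisions.append(decision)
    return decisions


def synthesize_gene_parent(ref_db: AnnotationDB, ref_gene_id: str,
                           gene_id: str, seqid: str, start: int, end: int,
                           strand: str) -> FeatureRecord:
    """Gene feature for a protein-based locus, copied from the reference
    gene so the gene -> mRNA -> exon/CDS hierarchy is restored."""
    ref_gene = ref_db[ref_gene_id]
    return ref_gene.copy(feature_id=gene_id, seqid=seqid, start=start,
                         end=end, strand=strand, parent_id=None)


def assign_copy_ids(accepted: list[LocusEntry],
                    taken_base_ids: set[str]) -> dict[str, tuple[str, int]]:
    """Stable ids for accepted copies: the first copy of an otherwise
    unmapped gene keeps the reference id; extras get ``_1``, ``_2``, ... in
    (seqid, start) order, with the ordinal as the extra-copy number."""
    out: dict[str, tuple[str, int]] = {}
    by_gene: dict[str, list[LocusEntry]] = {}
    for e in accepted:
        by_gene.setdefault(e.ref_gene_id, []).append(e)
    counters: dict[str, int] = {}
    for ref_gene_id in sorted(by_gene):
        entries = sorted(by_gene[ref_gene_id], key=lambda e: (e.seqid, e.start))
        for e in entries:
            if ref_gene_id not in taken_base_ids:
                out[e.locus_id] = (ref_gene_id, 0)
                taken_base_ids.add(ref_gene_id)
            else:
                k = counters.get(ref_gene_id, 0) + 1
                counters[ref_gene_id] = k
                out[e.locus_id] = (f"{ref_gene_id}_{k}", k)
    return out
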