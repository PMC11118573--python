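"""CDS chaining: merge two candidate CDS chains block by block.

Step 1 of the protein-maximization algorithm. Both candidate transcripts
(one from the DNA-alignment lift-over, one from the protein-alignment
lift-over) are translated and globally aligned to the reference protein.
Each candidate's CDS boundaries are mapped onto reference-protein
coordinates through its alignment; the two CDS lists are then partitioned
into paired groups that end wherever the cumulative number of aligned
reference residues is equal for both candidates. Within each paired block
the group with the higher partial (gap-compressed) identity is selected —
ties go to the DNA-based candidate so UTRs survive — and the selected
groups are concatenated into the merged CDS chain.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

from .annot_io import FeatureRecord, GenomeSequence
from .identity import (PairwiseAlignment, align_protein, partial_identity,
                       protein_identity)
from .seqtools import cds_phases, extract_spliced, translate

log = logging.getLogger(__name__)


@dataclass
class CdsBoundary:
    """Protein-coordinate interval of one CDS: on the candidate's own
    protein (qry) and, via the alignment, on the reference protein."""

    qry_aa_start: int
    qry_aa_end: int
    ref_aa_start: int
    ref_aa_end: int

    @property
    def zero_width(self) -> bool:
        return self.ref_aa_start == self.ref_aa_end


@dataclass
class CdsBoundaryMap:
    """Boundary intervals for a whole CDS chain, plus its alignment."""

    boundaries: list[CdsBoundary]
    alignment: PairwiseAlignment
    cds_list: list[FeatureRecord]

    @property
    def ref_ends(self) -> list[int]:
        return [b.ref_aa_end for b in self.boundaries]


@dataclass
class CdsGroup:
    """One side (dna or prot) of a comparison block."""

    source: str                      # 'dna' | 'prot'
    index: int                       # block number, 0-based
    cds_list: list[FeatureRecord]
    ref_span: tuple[int, int]        # reference aa interval [a, b)
    partial_id: float = 0.0

    @property
    def ref_aa_end(self) -> int:
        return self.ref_span[1]


@dataclass
class ChainSelection:
    """The merged chain: per-block winners and the concatenated CDS list."""

    selected: list[CdsGroup]
    merged_cds: list[FeatureRecord]          # 5'->3'
    merged_protein_id: float
    merged_protein: str
    winners: list[str] = field(default_factory=list)
    blocks: list[tuple[CdsGroup, CdsGroup]] = field(default_factory=list)


def order_5p_to_3p(cds_list: list[FeatureRecord], strand: str) -> list[FeatureRecord]:
    return sorted(cds_list, key=lambda c: c.start, reverse=(strand == "-"))


def candidate_protein(genome: GenomeSequence, cds_list: list[FeatureRecord],
                      strand: str, phase: int = 0) -> tuple[str, object]:
    """Translate a CDS chain. Returns (protein, SplicedSequence).

    The protein is the full translation (internal stops kept as ``*``) with
    a terminal stop stripped; the first ``phase`` bases are skipped when the
    chain starts mid-codon.
    """
    ordered = order_5p_to_3p(cds_list, strand)
    spliced = extract_spliced(genome, [(c.start, c.end) for c in ordered], strand)
    prot = translate(spliced.dna[phase:])
    if prot.endswith("*"):
        prot = prot[:-1]
    return prot, spliced


def map_cds_boundaries(aln: PairwiseAlignment, cds_list: list[FeatureRecord],
                       phase: int = 0) -> CdsBoundaryMap:
    """Express each CDS of a chain as a reference-protein interval.

    ``cds_list`` must be ordered 5'->3'; ``aln`` aligns the reference
    protein (ref row) to the chain's translation (qry row). Each CDS's
    nucleotide extent becomes a complete-codon interval on the candidate
    protein, which the alignment columns — walking past query-side gaps,
    i.e. the cigar-adjustment step — convert into counts of aligned
    reference residues.
    """
    qlen = len(aln.qry)
    # prefix counts per alignment column: residues consumed in each row
    qcum, rcum = [0], [0]
    for r, q in zip(aln.aligned_ref, aln.aligned_qry):
        qcum.append(qcum[-1] + (q != "-"))
        rcum.append(rcum[-1] + (r != "-"))

    def ref_count(q_boundary: int) -> int:
        if q_boundary <= 0:
            return 0
        col = bisect_left(qcum, q_boundary)
        return rcum[min(col, len(rcum) - 1)]

    boundaries = []
    cum_nt = -phase
    prev_q = 0
    for cds in cds_list:
        cum_nt += cds.length
        q_end = min(max(cum_nt // 3, 0), qlen)
        b = CdsBoundary(prev_q, q_end, ref_count(prev_q), ref_count(q_end))
        if b.zero_width:
            log.debug("CDS %s maps to a zero-width reference interval",
                      cds.feature_id)
        boundaries.append(b)
        prev_q = q_end
    return CdsBoundaryMap(boundaries, aln, cds_list)


def form_groups(dna_map: CdsBoundaryMap,
                prot_map: CdsBoundaryMap) -> list[tuple[CdsGroup, CdsGroup]]:
    """Partition both CDS lists into paired blocks ending at shared
    cumulative reference-residue counts; the final block always ends at the
    last CDS of both chains."""
    ends_l, ends_m = dna_map.ref_ends, prot_map.ref_ends
    if not ends_l or not ends_m:
        raise ValueError("both CDS chains must be non-empty")
    last_l, last_m = ends_l[-1], ends_m[-1]
    cut = min(last_l, last_m)
    # strictly-increasing values present as a CDS end in BOTH chains
    shared, i, j, prev = [], 0, 0, 0
    while i < len(ends_l) and j < len(ends_m):
        a, b = ends_l[i], ends_m[j]
        if a == b:
            if prev < a < cut:
                shared.append(a)
                prev = a
            i += 1
            j += 1
        elif a < b:
            i += 1
        else:
            j += 1
    boundaries = shared + [max(last_l, last_m)]

    def partition(bmap: CdsBoundaryMap) -> list[list[FeatureRecord]]:
        groups = [[] for _ in boundaries]
        k = 0
        for cds, bnd in zip(bmap.cds_list, bmap.boundaries):
            while k < len(boundaries) - 1 and bnd.ref_aa_end > boundaries[k]:
                k += 1
            groups[k].append(cds)
        return groups

    parts_l, parts_m = partition(dna_map), partition(prot_map)
    blocks = []
    prev = 0
    for k, bnd in enumerate(boundaries):
        span = (prev, bnd)
        blocks.append((CdsGroup("dna", k, parts_l[k], span),
                       CdsGroup("prot", k, parts_m[k], span)))
        prev = bnd
    return blocks


def _clamp_chain(cds_list: list[FeatureRecord], strand: str) -> list[FeatureRecord]:
    """Defensive: enforce strictly increasing (decreasing on -) coordinates
    at source-switch junctions by trimming, dropping emptied CDSs."""
    out: list[FeatureRecord] = []
    for cds in cds_list:
        if not out:
            out.append(cds)
            continue
        prev = out[-1]
        if strand == "+":
            if cds.start <= prev.end:
                if cds.end <= prev.end:
                    log.warning("dropping CDS %s swallowed at a chain junction",
                                cds.feature_id)
                    continue
                cds = cds.copy(start=prev.end + 1)
        else:
            if cds.end >= prev.start:
                if cds.start >= prev.start:
                    log.warning("dropping CDS %s swallowed at a chain junction",
                                cds.feature_id)
                    continue
                cds = cds.copy(end=prev.start - 1)
        out.append(cds)
    return out


def select_chain(blocks: list[tuple[CdsGroup, CdsGroup]],
                 dna_map: CdsBoundaryMap, prot_map: CdsBoundaryMap,
                 ref_protein: str, genome: GenomeSequence, strand: str,
                 dna_phase: int = 0, prot_phase: int = 0) -> ChainSelection:
    """Pick the higher-partial-identity group per block (ties -> dna) and
    concatenate the winners into the merged CDS chain."""
    selected, winners = [], []
    for gl, gm in blocks:
        gl.partial_id = (partial_identity(dna_map.alignment, gl.ref_span)
                         if gl.cds_list else 0.0)
        gm.partial_id = (partial_identity(prot_map.alignment, gm.ref_span)
                         if gm.cds_list else 0.0)
        win = gl if gl.partial_id >= gm.partial_id else gm
        selected.append(win)
        winners.append(win.source)

    merged = [cds.copy() for grp in selected for cds in grp.cds_list]
    merged = _clamp_chain(merged, strand)
    first_phase = dna_phase if winners and winners[0] == "dna" else prot_phase
    phases = cds_phases([c.length for c in merged], first_phase)
    for cds, ph in zip(merged, phases):
        cds.phase = ph
    if merged:
        prot, _ = candidate_protein(genome, merged, strand, first_phase)
        pid = protein_identity(ref_protein, prot) if prot else 0.0
    else:
        prot, pid = "", 0.0
    return ChainSelection(selected, merged, pid, prot, winners, blocks)


def reconcile_pair(ref_protein: str, genome: GenomeSequence,
                   dna_cds: list[FeatureRecord], prot_cds: list[FeatureRecord],
                   strand: str, dna_phase: int = 0,
                   prot_phase: int = 0) -> ChainSelection:
    """Full chaining of one transcript pair; falls back to the DNA candidate
    when the two candidates disagree on contig or strand, and to whichever
    candidate exists when the other is absent."""

    def trivial(cds_list, source, phase):
        ordered = order_5p_to_3p(cds_list, strand)
        prot, _ = candidate_protein(genome, ordered, strand, phase)
        pid = protein_identity(ref_protein, prot) if prot else 0.0
        grp = CdsGroup(source, 0, ordered, (0, len(ref_protein)), pid)
        merged = [c.copy() for c in ordered]
        for c, ph in zip(merged, cds_phases([c.length for c in merged], phase)):
            c.phase = ph
        return ChainSelection([grp], merged, pid, prot, [source], [])

    if not prot_cds:
        return trivial(dna_cds, "dna", dna_phase)
    if not dna_cds:
        return trivial(prot_cds, "prot", prot_phase)
    if ({c.seqid for c in dna_cds} != {c.seqid for c in prot_cds}
            or {c.strand for c in dna_cds} != {c.strand for c in prot_cds}):
        log.info("candidates on different contig/strand; DNA candidate kept")
        return trivial(dna_cds, "dna", dna_phase)

    dna_ordered = order_5p_to_3p(dna_cds, strand)
    prot_ordered = order_5p_to_3p(prot_cds, strand)
    dna_prot, _ = candidate_protein(genome, dna_ordered, strand, dna_phase)
    prot_prot, _ = candidate_protein(genome, prot_ordered, strand, prot_phase)
    if not dna_prot:
        return trivial(prot_cds, "prot", prot_phase)
    if not prot_prot:
        return trivial(dna_cds, "dna", dna_phase)
    aln_dna = align_protein(ref_protein, dna_prot)
    aln_prot = align_protein(ref_protein, prot_prot)
    dna_map = map_cds_boundaries(aln_dna, dna_ordered, dna_phase)
    prot_map = map_cds_boundaries(aln_prot, prot_ordered, prot_phase)
    blocks = form_groups(dna_map, prot_map)
    return select_chain(blocks, dna_map, prot_map, ref_protein, genome,
                        strand, dna_phase, prot_phase)
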