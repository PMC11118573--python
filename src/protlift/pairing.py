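"""Pairing of protein-alignment transcripts with DNA-alignment transcripts.

A protein-to-genome aligner maps each reference protein independently and
knows nothing about gene loci, so one reference transcript may map to
several places (extra copies, pseudogenes, read-throughs). Pairing finds,
for each reference transcript, the protein-based mapping that belongs to
the DNA-based lift-over locus of the same transcript:

1. the two candidates' loci must overlap (same contig and strand), and
2. the protein-based candidate must not overlap any *other* DNA-based gene
   locus, except loci that the matched gene locus itself also overlaps;

mappings that straddle two or more distinct DNA-based gene loci are removed
as "read-through" artifacts, and among surviving candidates the one with
the highest protein identity to the reference is chosen.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field

from .annot_io import AnnotationDB, GenomeSequence
from .chaining import candidate_protein, order_5p_to_3p
from .identity import protein_identity

log = logging.getLogger(__name__)

#: Suffix appended to protein-based transcript ids when one reference
#: protein maps to several places (configurable; aligner-version dependent).
DEFAULT_SUFFIX_PATTERN = r"_ditto\d+$"

#: Suffix convention for extra copies in DNA-based (Liftoff-style) output.
COPY_SUFFIX_PATTERN = r"_\d+$"


@dataclass
class TranscriptPair:
    """One reference transcript and its candidate mappings on the target."""

    ref_transcript_id: str
    dna_tx_id: str | None = None
    prot_candidate_ids: list[str] = field(default_factory=list)
    chosen_prot: int | None = None
    status: str = "unmapped"        # both | dna_only | prot_only | unmapped
    candidate_identities: dict[str, float] = field(default_factory=dict)

    @property
    def chosen_prot_id(self) -> str | None:
        if self.chosen_prot is None:
            return None
        return self.prot_candidate_ids[self.chosen_prot]


def base_id(tx_id: str, suffix_pattern: str) -> str:
    return re.sub(suffix_pattern, "", tx_id)


def _tx_locus(db: AnnotationDB, tx_id: str) -> tuple[str, int, int, str]:
    """(seqid, start, end, strand) of a transcript's gene locus (the
    transcript's own span when it has no gene parent)."""
    tx = db[tx_id]
    if tx.parent_id is not None and tx.parent_id in db:
        g = db[tx.parent_id]
        return g.seqid, g.start, g.end, g.strand
    return tx.seqid, tx.start, tx.end, tx.strand


def match_transcripts(dna_db: AnnotationDB, prot_db: AnnotationDB,
                      suffix_pattern: str = DEFAULT_SUFFIX_PATTERN,
                      ) -> dict[str, TranscriptPair]:
    """Build a :class:`TranscriptPair` for every reference transcript id seen
    in either candidate annotation, applying overlap conditions (1) and (2)."""
    pairs: dict[str, TranscriptPair] = {}

    dna_primary: dict[str, str] = {}
    for tx in dna_db.transcripts():
        ecn = tx.attributes.get("extra_copy_number")
        if ecn is not None:
            primary = ecn == "0"
        else:
            primary = base_id(tx.feature_id, COPY_SUFFIX_PATTERN) == tx.feature_id
        if primary:
            dna_primary[tx.feature_id] = tx.feature_id

    prot_by_base: dict[str, list[str]] = {}
    for tx in prot_db.transcripts():
        prot_by_base.setdefault(base_id(tx.feature_id, suffix_pattern),
                                []).append(tx.feature_id)
    for cand_list in prot_by_base.values():
        cand_list.sort(key=lambda t: (prot_db[t].seqid, prot_db[t].start))

    for ref_id in sorted(set(dna_primary) | set(prot_by_base)):
        pair = TranscriptPair(ref_id)
        pair.dna_tx_id = dna_primary.get(ref_id)
        gene_hits: set[str] = set()
        if pair.dna_tx_id is not None:
            seqid, gs, ge, strand = _tx_locus(dna_db, pair.dna_tx_id)
            gene_hits = set(dna_db.genes_overlapping(seqid, gs, ge, strand))
            matched_gene = (dna_db[pair.dna_tx_id].parent_id
                            if dna_db[pair.dna_tx_id].parent_id in dna_db.features
                            else None)
        for cand in prot_by_base.get(ref_id, []):
            c = prot_db[cand]
            if pair.dna_tx_id is None:
                pair.prot_candidate_ids.append(cand)
                continue
            if c.seqid != seqid or c.strand != strand:
                continue
            if c.end < gs or c.start > ge:
                continue                                   # condition (1)
            others = set(dna_db.genes_overlapping(c.seqid, c.start, c.end,
                                                  c.strand))
            others.discard(matched_gene)
            if others - gene_hits:
                log.debug("protein candidate %s overlaps unrelated locus; dropped",
                          cand)
                continue                                   # condition (2)
            pair.prot_candidate_ids.append(cand)
        if pair.dna_tx_id and pair.prot_candidate_ids:
            pair.status = "both"
        elif pair.dna_tx_id:
            pair.status = "dna_only"
        elif pair.prot_candidate_ids:
            pair.status = "prot_only"
        pairs[ref_id] = pair
    return pairs


def resolve_multicopy(pair: TranscriptPair, ref_protein: str,
                      target_genome: dict[str, GenomeSequence],
                      dna_db: AnnotationDB, prot_db: AnnotationDB,
                      ) -> TranscriptPair:
    """Remove read-through candidates and choose the highest-identity one.

    A candidate spanning two or more distinct DNA-based gene loci is an
    erroneous read-through and is removed regardless of its identity. Ties
    break to the leftmost genomic start.
    """
    if not pair.prot_candidate_ids:
        return pair
    survivors: list[str] = []
    for cand in pair.prot_candidate_ids:
        c = prot_db[cand]
        hit = dna_db.genes_overlapping(c.seqid, c.start, c.end, c.strand)
        if len(hit) >= 2:
            log.debug("candidate %s spans %d gene loci; removed as read-through",
                      cand, len(hit))
            continue
        survivors.append(cand)
    pair.prot_candidate_ids = survivors
    if not survivors:
        pair.chosen_prot = None
        pair.status = "dna_only" if pair.dna_tx_id else "unmapped"
        return pair

    scored = []
    for idx, cand in enumerate(survivors):
        tx = prot_db[cand]
        cds = order_5p_to_3p(prot_db.cds_of(cand), tx.strand)
        if not cds or tx.seqid not in target_genome:
            ident = 0.0
        else:
            phase = cds[0].phase or 0
            prot, _ = candidate_protein(target_genome[tx.seqid], cds,
                                        tx.strand, phase)
            ident = protein_identity(ref_protein, prot) if prot else 0.0
        pair.candidate_identities[cand] = ident
        scored.append((-ident, tx.seqid, tx.start, idx))
    scored.sort()
    pair.chosen_prot = scored[0][3]
    pair.status = "both" if pair.dna_tx_id else "prot_only"
    return pair
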