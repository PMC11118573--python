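"""ORF search and repair, and per-transcript mutation classification.

Step 2 of the protein-maximization algorithm. Transcripts whose mutation
report contains a deleterious category (frameshift, stop gain, stop loss,
start loss) get an open-reading-frame search over the full spliced
transcript (exons including UTRs, so new starts in the 5' UTR and new
stops in the 3' UTR are reachable): in each of the three frames the
longest ATG-initiated ORF is retained, candidates are scored by
gap-compressed protein identity to the reference protein, and the CDS
boundaries are rewritten only when that does not decrease identity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from functools import lru_cache

from Bio import Align

from .identity import PairwiseAlignment, protein_identity, truncate_at_stop
from .seqtools import (START_CODON, SplicedSequence, translate)

log = logging.getLogger(__name__)

#: All mutation categories, in report order.
CATEGORIES = (
    "identical", "synonymous", "nonsynonymous", "inframe_insertion",
    "inframe_deletion", "frameshift", "stop_gain", "stop_loss", "start_loss",
)

#: Categories that trigger the ORF search.
DELETERIOUS = frozenset({"frameshift", "stop_gain", "stop_loss", "start_loss"})


@dataclass
class MutationReport:
    transcript_id: str
    categories: set[str] = field(default_factory=set)

    @property
    def deleterious(self) -> bool:
        return bool(self.categories & DELETERIOUS)

    def __post_init__(self):
        if "identical" in self.categories and len(self.categories) > 1:
            raise ValueError("'identical' is exclusive of all other categories")


@dataclass
class OrfCandidate:
    """An ATG-initiated ORF on a spliced transcript sequence.

    ``end_offset`` points one past the stop codon, or to the end of the last
    complete codon when no in-frame stop exists (stop-loss scenario).
    """

    frame: int
    start_offset: int
    end_offset: int
    protein: str            # without the terminal stop
    has_stop: bool
    identity_vs_ref: float = 0.0

    @property
    def nt_length(self) -> int:
        return self.end_offset - self.start_offset


@lru_cache(maxsize=1)
def _classify_aligner() -> Align.PairwiseAligner:
    """Affine-gap DNA aligner for indel classification. Unlike the
    identity-scoring alignment (whose linear gap costs may scatter one
    planted indel into several runs), a real gap-open cost keeps each
    mutational event as a single cigar run."""
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -2
    a.open_gap_score = -5
    a.extend_gap_score = -1
    return a


def _indel_events(ref_cds: str, tgt_cds: str) -> list[tuple[str, int]]:
    aln = _classify_aligner().align(ref_cds, tgt_cds)[0]
    cigar = PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score)).cigar
    return [(op, n) for op, n in cigar if op in ("I", "D")]


def classify_mutations(transcript_id: str, ref_tx_dna: str, tgt_tx_dna: str,
                       ref_cds_dna: str, tgt_cds_dna: str) -> MutationReport:
    """Classify the differences between a mapped transcript and its reference.

    "identical" means the transcript-level DNA (exons, UTRs included) is
    byte-equal. All other categories are derived from the CDS sequences:
    indel length mod 3 separates in-frame indels from frameshifts, codon
    comparison separates synonymous from non-synonymous substitutions, and
    the stop/start categories compare translation endpoints. Every
    non-identical transcript receives at least one category.
    """
    if ref_tx_dna == tgt_tx_dna:
        return MutationReport(transcript_id, {"identical"})
    cats: set[str] = set()
    ref_p_full = translate(ref_cds_dna)
    tgt_p_full = translate(tgt_cds_dna)
    ref_p = truncate_at_stop(ref_p_full)
    tgt_p = truncate_at_stop(tgt_p_full)

    if ref_cds_dna.startswith(START_CODON) and not tgt_cds_dna.startswith(START_CODON):
        cats.add("start_loss")

    has_indel = False
    if ref_cds_dna != tgt_cds_dna:
        for op, n in _indel_events(ref_cds_dna, tgt_cds_dna):
            has_indel = True
            if op == "I":
                cats.add("inframe_insertion" if n % 3 == 0 else "frameshift")
            else:
                cats.add("inframe_deletion" if n % 3 == 0 else "frameshift")

    # stop categories: a stop anywhere before the end of the target
    # translation is a gain (an in-frame deletion merely moves the terminal
    # stop and is not); a translation that never stops while the reference
    # does is a loss.
    tgt_stop_at = tgt_p_full.find("*")
    if tgt_stop_at != -1:
        if tgt_stop_at < len(tgt_p_full) - 1:
            cats.add("stop_gain")
    elif "*" in ref_p_full:
        cats.add("stop_loss")

    if not has_indel:
        if len(ref_cds_dna) == len(tgt_cds_dna):
            for i in range(0, len(ref_cds_dna) - 2, 3):
                ra = translate(ref_cds_dna[i:i + 3])
                ta = translate(tgt_cds_dna[i:i + 3])
                if ra == ta:
                    continue
                if ta == "*" or ra == "*":
                    continue        # covered by the stop categories
                if i == 0 and "start_loss" in cats:
                    continue
                cats.add("nonsynonymous")
        elif ref_cds_dna != tgt_cds_dna:
            cats.add("nonsynonymous")

    if not cats:
        # DNA differs (possibly only in UTRs or silent codon positions)
        # but the protein is intact
        cats.add("synonymous" if tgt_p == ref_p else "nonsynonymous")
    return MutationReport(transcript_id, cats)


def find_orfs(spliced_dna: str) -> list[OrfCandidate]:
    """Longest ATG-initiated ORF in each of the three reading frames.

    Within a frame, an ORF runs from an ATG to the end of the next in-frame
    stop codon; with no stop it extends to the last complete codon. Length
    ties go to the leftmost start. Frames with no ATG yield no candidate.
    """
    out = []
    n = len(spliced_dna)
    for frame in range(3):
        best: tuple[int, int, bool] | None = None   # (start, end, has_stop)
        open_start: int | None = None
        i = frame
        while i + 3 <= n:
            codon = spliced_dna[i:i + 3]
            if open_start is None and codon == START_CODON:
                open_start = i
            elif open_start is not None and translate(codon) == "*":
                cand = (open_start, i + 3, True)
                if best is None or cand[1] - cand[0] > best[1] - best[0]:
                    best = cand
                open_start = None
            i += 3
        if open_start is not None:
            cand = (open_start, i, False)
            if best is None or cand[1] - cand[0] > best[1] - best[0]:
                best = cand
        if best is not None:
            s, e, stopped = best
            prot = translate(spliced_dna[s:e])
            if prot.endswith("*"):
                prot = prot[:-1]
            out.append(OrfCandidate(frame, s, e, prot, stopped))
    return out


@dataclass
class RepairResult:
    changed: bool
    cds_intervals: list[tuple[int, int]]    # genomic, ascending
    protein: str
    identity: float
    orf: OrfCandidate | None = None


def _is_clean(cds_dna: str) -> bool:
    """A CDS chain whose translation is a well-formed ORF: starts with ATG,
    no internal stop, ends exactly at a stop codon."""
    if not cds_dna.startswith(START_CODON) or len(cds_dna) % 3 != 0:
        return False
    p = translate(cds_dna)
    return p.endswith("*") and "*" not in p[:-1]


def orf_repair(spliced: SplicedSequence, cds_intervals: list[tuple[int, int]],
               cds_dna: str, ref_protein: str, report: MutationReport,
               current_frame: int | None = None) -> RepairResult:
    """Re-derive CDS boundaries from the best ORF on the spliced transcript.

    ``spliced`` is the search domain (exon-level sequence when the
    transcript has exons, else the CDS chain itself); ``cds_intervals`` and
    ``cds_dna`` describe the current annotation. The update is applied only
    when the best ORF's identity to the reference protein strictly exceeds
    the current one, or equals it while the ORF is a well-formed
    start-to-stop frame and the current annotation is not.
    """
    pre_protein = translate(cds_dna)
    if pre_protein.endswith("*"):
        pre_protein = pre_protein[:-1]
    pre_id = protein_identity(ref_protein, pre_protein) if pre_protein else 0.0
    unchanged = RepairResult(False, sorted(cds_intervals), pre_protein, pre_id)
    if not report.deleterious:
        return unchanged

    candidates = find_orfs(spliced.dna)
    if not candidates:
        log.info("%s: no ATG in any frame; annotation unchanged",
                 report.transcript_id)
        return unchanged
    for cand in candidates:
        cand.identity_vs_ref = (protein_identity(ref_protein, cand.protein)
                                if cand.protein else 0.0)

    def rank(c: OrfCandidate):
        frame_pref = 0 if (current_frame is not None and c.frame == current_frame) else 1
        return (-c.identity_vs_ref, frame_pref, c.frame, c.start_offset)

    best = min(candidates, key=rank)
    better = best.identity_vs_ref > pre_id
    tie_clean = (best.identity_vs_ref == pre_id and best.has_stop
                 and best.protein.startswith("M") and not _is_clean(cds_dna))
    if not (better or tie_clean):
        log.info("%s: no ORF improves on the annotation (best %.4f vs %.4f)",
                 report.transcript_id, best.identity_vs_ref, pre_id)
        return unchanged
    new_cds = spliced.project_interval(best.start_offset, best.end_offset)
    return RepairResult(True, new_cds, best.protein, best.identity_vs_ref, best)
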