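"""Spliced transcript/CDS sequence extraction, coordinate maps and translation.

A :class:`SplicedSequence` is the 5'->3' concatenation of a transcript's
exon (or CDS) intervals, together with an invertible map between positions
in the spliced sequence and genomic coordinates.  The map is what lets the
ORF search rewrite CDS boundaries: an ORF found on the spliced sequence is
projected back to a list of genomic intervals.
"""

from __future__ import annotations

from dataclasses import dataclass

from Bio.Data import CodonTable

_TABLE1 = CodonTable.unambiguous_dna_by_id[1]
CODON_TO_AA: dict[str, str] = dict(_TABLE1.forward_table)
for _stop in _TABLE1.stop_codons:
    CODON_TO_AA[_stop] = "*"

STOP_CODONS = tuple(_TABLE1.stop_codons)   # TAA, TAG, TGA
START_CODON = "ATG"

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(dna: str) -> str:
    return dna.translate(_COMP)[::-1]


def translate(dna: str, to_first_stop: bool = False) -> str:
    """Standard-code translation; stops render ``*``; codons with N render ``X``.

    Trailing 1-2 nt are ignored. With ``to_first_stop``, output is truncated
    immediately after the first ``*``.
    """
    aas = []
    for i in range(0, len(dna) - 2, 3):
        codon = dna[i:i + 3]
        aa = CODON_TO_AA.get(codon, "X")
        aas.append(aa)
        if to_first_stop and aa == "*":
            break
    return "".join(aas)


@dataclass
class SplicedSequence:
    """Spliced sequence with its genomic segment map.

    ``segments`` is ordered 5'->3'; each entry is
    ``(genomic_start, genomic_end, offset)`` with 1-based inclusive genomic
    coordinates and ``offset`` the position of the segment's first (5'-most)
    base within ``dna``. On the minus strand segments run in descending
    genomic order and ``dna`` is the reverse complement of the ascending
    concatenation.
    """

    transcript_id: str
    dna: str
    segments: list[tuple[int, int, int]]
    strand: str
    seqid: str

    def __len__(self) -> int:
        return len(self.dna)

    # offset <-> genomic -----------------------------------------------

    def genomic_to_offset(self, gpos: int) -> int:
        for gstart, gend, off in self.segments:
            if gstart <= gpos <= gend:
                if self.strand == "+":
                    return off + (gpos - gstart)
                return off + (gend - gpos)
        raise ValueError(
            f"position {gpos} not in any segment of {self.transcript_id!r}")

    def offset_to_genomic(self, offset: int) -> int:
        if not 0 <= offset < len(self.dna):
            raise ValueError(f"offset {offset} outside spliced sequence")
        for gstart, gend, off in self.segments:
            seglen = gend - gstart + 1
            if off <= offset < off + seglen:
                if self.strand == "+":
                    return gstart + (offset - off)
                return gend - (offset - off)
        raise AssertionError("segment map does not cover its own sequence")

    def project_interval(self, t0: int, t1: int) -> list[tuple[int, int]]:
        """Genomic intervals (ascending, 1-based inclusive) for spliced
        offsets ``[t0, t1)``."""
        if not (0 <= t0 < t1 <= len(self.dna)):
            raise ValueError(f"bad spliced interval [{t0}, {t1})")
        out = []
        for gstart, gend, off in self.segments:
            seglen = gend - gstart + 1
            lo = max(t0, off)
            hi = min(t1, off + seglen)
            if lo >= hi:
                continue
            if self.strand == "+":
                out.append((gstart + (lo - off), gstart + (hi - 1 - off)))
            else:
                out.append((gend - (hi - 1 - off), gend - (lo - off)))
        out.sort()
        return out

    def genomic_to_protein_coord(self, gpos: int) -> tuple[int, int]:
        """(amino-acid index, offset within codon) for a genomic position."""
        return divmod(self.genomic_to_offset(gpos), 3)


def extract_spliced(genome, intervals: list[tuple[int, int]], strand: str,
                    transcript_id: str = "") -> SplicedSequence:
    """Concatenate genomic intervals into a 5'->3' spliced sequence.

    ``genome`` is a :class:`~protlift.annot_io.GenomeSequence`. Intervals are
    1-based inclusive, must lie within the contig and must not overlap.
    """
    seq = genome.sequence
    ivs = sorted(intervals)
    for (s, e) in ivs:
        if s < 1 or e > len(seq):
            raise ValueError(
                f"interval ({s},{e}) outside contig {genome.seqid} (len {len(seq)})")
    for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
        if s2 <= e1:
            raise ValueError(f"overlapping intervals ({s1},{e1}) and ({s2},{e2})")
    if strand == "+":
        ordered = ivs
    else:
        ordered = ivs[::-1]
    dna_parts, segments, off = [], [], 0
    for (s, e) in ordered:
        part = seq[s - 1:e]
        if strand == "-":
            part = revcomp(part)
        dna_parts.append(part)
        segments.append((s, e, off))
        off += e - s + 1
    return SplicedSequence(transcript_id, "".join(dna_parts), segments,
                           strand, genome.seqid)


def cds_phases(lengths: list[int], initial_phase: int = 0) -> list[int]:
    """GFF3 phases for a 5'->3' CDS chain, recomputed from cumulative length."""
    phases, cum = [], 0
    for n in lengths:
        phases.append((3 - (cum - initial_phase) % 3) % 3)
        cum += n
    return phases
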