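"""Pairwise alignment and sequence-identity metrics.

Three metrics drive the reconciliation engine:

* **DNA identity** — BLAST-style: matching bases over alignment columns,
  gap columns counted in the denominator. Scoring: match +1, mismatch -3,
  gap open 2, gap extend 2 (global alignment).
* **Gap-compressed protein identity** — exact residue matches over columns,
  where each maximal run of columns gapped in the *reference* row counts as
  a single column. This prevents over-penalizing target proteins that come
  out longer than the reference (repeat expansions, truncated reference
  proteins). The target protein is truncated at its first stop codon before
  alignment, so residues downstream of a premature stop cannot match and
  the uncovered reference tail stays in the denominator. Scoring: BLOSUM62,
  gap open 11, gap extend 2.
* **Partial identity** — the same gap-compressed formula restricted to the
  alignment columns covering a span of reference residues; this is the
  score the chaining algorithm compares per CDS group.

Alignment is global (Needleman-Wunsch, affine gaps) via
Bio.Align.PairwiseAligner; the open penalty applies to the first gap
residue and the extend penalty to each one after it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

from Bio import Align
from Bio.Align import substitution_matrices

#: Amino-acid alphabet accepted by the protein aligner.
PROTEIN_ALPHABET = "ARNDCQEGHILKMFPSTWYVBZX*"


@dataclass
class PairwiseAlignment:
    """A global pairwise alignment as two equal-length gapped strings."""

    aligned_ref: str
    aligned_qry: str
    score: float

    def __post_init__(self):
        if len(self.aligned_ref) != len(self.aligned_qry):
            raise ValueError("aligned rows differ in length")

    @property
    def ncols(self) -> int:
        return len(self.aligned_ref)

    @property
    def cigar(self) -> list[tuple[str, int]]:
        """Run-length ops: M (match/mismatch), I (gap in ref), D (gap in qry)."""
        ops = []
        for r, q in zip(self.aligned_ref, self.aligned_qry):
            if r == "-" and q == "-":
                raise ValueError("gap/gap column")
            op = "I" if r == "-" else ("D" if q == "-" else "M")
            if ops and ops[-1][0] == op:
                ops[-1][1] += 1
            else:
                ops.append([op, 1])
        return [(op, n) for op, n in ops]

    @property
    def ref(self) -> str:
        return self.aligned_ref.replace("-", "")

    @property
    def qry(self) -> str:
        return self.aligned_qry.replace("-", "")


@lru_cache(maxsize=1)
def _dna_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = 1
    a.mismatch_score = -3
    a.open_gap_score = -2
    a.extend_gap_score = -2
    return a


@lru_cache(maxsize=1)
def protein_matrix():
    """BLOSUM62 with X scoring 0 against everything and ``*`` matching only
    itself (+1; -4 otherwise, including against X)."""
    m = substitution_matrices.load("BLOSUM62")
    for c in m.alphabet:
        m["X", c] = m[c, "X"] = 0.0
    for c in m.alphabet:
        m["*", c] = m[c, "*"] = -4.0
    m["*", "*"] = 1.0
    return m


@lru_cache(maxsize=1)
def _protein_aligner() -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.substitution_matrix = protein_matrix()
    a.open_gap_score = -11
    a.extend_gap_score = -2
    return a


def _align(aligner, ref: str, qry: str) -> PairwiseAlignment:
    if not ref or not qry:
        raise ValueError("cannot align empty sequence")
    aln = aligner.align(ref, qry)[0]
    return PairwiseAlignment(str(aln[0]), str(aln[1]), float(aln.score))


def align_dna(ref: str, qry: str) -> PairwiseAlignment:
    """Global DNA alignment: match 1, mismatch -3, gap open 2, extend 2."""
    return _align(_dna_aligner(), ref, qry)


def align_protein(ref: str, qry: str) -> PairwiseAlignment:
    """Global protein alignment: BLOSUM62, gap open 11, extend 2.

    Internal stop codons may be present in ``qry`` as ``*`` — they align as
    ordinary (heavily penalized) residues, which is what the chaining step
    needs to keep scoring blocks downstream of a premature stop.
    """
    return _align(_protein_aligner(), ref, qry)


# -- metrics -------------------------------------------------------------

def dna_identity(aln: PairwiseAlignment) -> float:
    """Matching bases over total alignment columns (gaps in denominator)."""
    if aln.ncols == 0:
        return 0.0
    matches = sum(1 for r, q in zip(aln.aligned_ref, aln.aligned_qry)
                  if r == q and r != "-")
    return matches / aln.ncols


def gap_compressed_identity(aln: PairwiseAlignment) -> float:
    """Exact matches over columns, each maximal reference-gap run counting once."""
    matches = 0
    denom = 0
    in_ref_gap = False
    for r, q in zip(aln.aligned_ref, aln.aligned_qry):
        if r == "-":
            if not in_ref_gap:
                denom += 1
                in_ref_gap = True
        else:
            in_ref_gap = False
            denom += 1
            if r == q:
                matches += 1
    return matches / denom if denom else 0.0


def truncate_at_stop(protein: str) -> str:
    """The prefix of a protein up to (excluding) its first stop."""
    i = protein.find("*")
    return protein if i < 0 else protein[:i]


def protein_identity(ref_protein: str, qry_protein: str) -> float:
    """Gap-compressed identity of a target protein against the reference.

    The query is truncated at its first stop codon, then globally aligned
    to the full reference; reference residues left uncovered by a truncated
    query therefore stay in the denominator.
    """
    if not ref_protein:
        raise ValueError("empty reference protein")
    qry = truncate_at_stop(qry_protein)
    if not qry:
        return 0.0
    return gap_compressed_identity(align_protein(ref_protein, qry))


def partial_identity(aln: PairwiseAlignment,
                     ref_span: tuple[int, int],
                     qry_span: tuple[int, int] | None = None) -> float:
    """Gap-compressed identity restricted to reference residues [a, b).

    Columns where the reference is gapped (query insertions) are attributed
    to the span of the reference residue immediately 5' of the run (runs
    before the first residue go with span start 0) and each run counts once
    in the denominator. With ``qry_span``, columns must also fall inside the
    given query-residue interval.
    """
    a, b = ref_span
    ref_len = len(aln.ref)
    if not (0 <= a <= b <= ref_len):
        raise ValueError(f"span [{a}, {b}) outside reference of length {ref_len}")
    if a == b:
        return 0.0
    qa, qb = qry_span if qry_span is not None else (0, len(aln.qry))
    matches = 0
    denom = 0
    r_idx = 0  # reference residues consumed so far
    q_idx = 0
    in_counted_gap_run = False
    for r, q in zip(aln.aligned_ref, aln.aligned_qry):
        if r == "-":
            attach = r_idx - 1 if r_idx > 0 else 0
            if a <= attach < b and qa <= q_idx < qb:
                if not in_counted_gap_run:
                    denom += 1
                    in_counted_gap_run = True
            q_idx += 1
            continue
        in_counted_gap_run = False
        this_r = r_idx
        r_idx += 1
        if not (a <= this_r < b):
            if q != "-":
                q_idx += 1
            continue
        if q == "-":
            denom += 1
            continue
        if qa <= q_idx < qb:
            denom += 1
            if r == q:
                matches += 1
        q_idx += 1
    return matches / denom if denom else 0.0
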