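"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written from scratch against the *stated
definitions* (full-matrix affine DP with exhaustive co-optimal enumeration,
column-walk identity counting, all-starts ORF scan) and shares no code with
the package internals it checks.
"""

from __future__ import annotations

import itertools

NEG_INF = float("-inf")


def affine_align_all(ref: str, qry: str, score, open_pen: float,
                     extend_pen: float, max_paths: int = 5000):
    """All co-optimal global alignments under affine gap costs.

    ``score(a, b)`` scores a substitution column; a gap of length L costs
    ``open + (L-1) * extend``. Returns ``(best_score, alignments)`` where
    each alignment is a pair of equal-length gapped strings.
    """
    n, m = len(ref), len(qry)
    M = [[NEG_INF] * (m + 1) for _ in range(n + 1)]
    Ix = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in qry (consumes ref)
    Iy = [[NEG_INF] * (m + 1) for _ in range(n + 1)]  # gap in ref (consumes qry)
    M[0][0] = 0.0
    for i in range(1, n + 1):
        Ix[i][0] = -open_pen - (i - 1) * extend_pen
    for j in range(1, m + 1):
        Iy[0][j] = -open_pen - (j - 1) * extend_pen
    for i in range(n + 1):
        for j in range(m + 1):
            if i > 0 and j > 0:
                best = max(M[i - 1][j - 1], Ix[i - 1][j - 1], Iy[i - 1][j - 1])
                M[i][j] = best + score(ref[i - 1], qry[j - 1])
            if i > 0 and (i, j) != (1, 0):
                Ix[i][j] = max(Ix[i][j],
                               M[i - 1][j] - open_pen,
                               Ix[i - 1][j] - extend_pen,
                               Iy[i - 1][j] - open_pen)
            if j > 0 and (i, j) != (0, 1):
                Iy[i][j] = max(Iy[i][j],
                               M[i][j - 1] - open_pen,
                               Ix[i][j - 1] - open_pen,
                               Iy[i][j - 1] - extend_pen)
    best = max(M[n][m], Ix[n][m], Iy[n][m])

    sols: list[tuple[str, str]] = []

    def walk(i, j, state, aref, aqry):
        if len(sols) >= max_paths:
            return
        if i == 0 and j == 0 and state == "M":
            sols.append((aref[::-1], aqry[::-1]))
            return
        eps = 1e-9
        if state == "M":
            if i > 0 and j > 0:
                s = score(ref[i - 1], qry[j - 1])
                for prev in ("M", "Ix", "Iy"):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i - 1][j - 1]
                    if abs(val + s - M[i][j]) < eps and val > NEG_INF:
                        walk(i - 1, j - 1, prev, aref + ref[i - 1],
                             aqry + qry[j - 1])
        elif state == "Ix":
            if i > 0:
                for prev, pen in (("M", open_pen), ("Ix", extend_pen),
                                  ("Iy", open_pen)):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i - 1][j]
                    if abs(val - pen - Ix[i][j]) < eps and val > NEG_INF:
                        walk(i - 1, j, prev, aref + ref[i - 1], aqry + "-")
        else:
            if j > 0:
                for prev, pen in (("M", open_pen), ("Ix", open_pen),
                                  ("Iy", extend_pen)):
                    val = {"M": M, "Ix": Ix, "Iy": Iy}[prev][i][j - 1]
                    if abs(val - pen - Iy[i][j]) < eps and val > NEG_INF:
                        walk(i, j - 1, prev, aref + "-", aqry + qry[j - 1])

    for state, mat in (("M", M), ("Ix", Ix), ("Iy", Iy)):
        if abs(mat[n][m] - best) < 1e-9:
            walk(n, m, state, "", "")
    # the i==0/j==0 boundary walks terminate in gap states; accept those too
    if not sols:
        raise AssertionError("traceback found no path")
    return best, sols


def dna_score(a: str, b: str) -> float:
    return 1.0 if a == b else -3.0


def make_protein_score(matrix):
    def score(a, b):
        return float(matrix[a, b])
    return score


def oracle_dna_identity(aref: str, aqry: str) -> float:
    matches = sum(1 for a, b in zip(aref, aqry) if a == b and a != "-")
    return matches / len(aref)


def oracle_gap_compressed(aref: str, aqry: str) -> float:
    """Column-walk re-implementation of gap-compressed identity."""
    matches = denom = 0
    for is_gap, cols in itertools.groupby(zip(aref, aqry),
                                          key=lambda c: c[0] == "-"):
        cols = list(cols)
        if is_gap:
            denom += 1
        else:
            denom += len(cols)
            matches += sum(1 for a, b in cols if a == b)
    return matches / denom if denom else 0.0


def oracle_partial_identity(aref: str, aqry: str, a: int, b: int) -> float:
    """Column-walk partial identity over reference residues [a, b);
    reference-gap runs attach to the residue on their 5' side."""
    cols = []        # (kind, ref_idx, match) — kind: 'res' or 'gap'
    r = 0
    for x, y in zip(aref, aqry):
        if x == "-":
            cols.append(("gap", max(r - 1, 0), False))
        else:
            cols.append(("res", r, x == y))
            r += 1
    matches = denom = 0
    prev_gap_counted = False
    for kind, idx, match in cols:
        if not (a <= idx < b):
            prev_gap_counted = False
            continue
        if kind == "gap":
            if not prev_gap_counted:
                denom += 1
                prev_gap_counted = True
        else:
            prev_gap_counted = False
            denom += 1
            matches += match
    return matches / denom if denom else 0.0


def oracle_find_orfs(dna: str):
    """All-starts scan: for each frame, every ATG paired with its next
    in-frame stop (or the sequence end); return the longest per frame."""
    stops = {"TAA", "TAG", "TGA"}
    best = {}
    for frame in range(3):
        for s in range(frame, len(dna) - 2, 3):
            if dna[s:s + 3] != "ATG":
                continue
            end, has_stop = None, False
            for e in range(s + 3, len(dna) - 2, 3):
                if dna[e:e + 3] in stops:
                    end, has_stop = e + 3, True
                    break
            if end is None:
                end = s + ((len(dna) - s) // 3) * 3
            cand = (end - s, -s, s, end, has_stop)
            if frame not in best or cand[:2] > best[frame][:2]:
                best[frame] = cand
    return {f: (s, e, stop) for f, (_, _, s, e, stop) in best.items()}
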