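"""Independent brute-force oracles used to check the implementation.

Everything here is written from the definitions, independently of the
package's own code paths: a plain Gotoh affine-gap DP, a plain
Smith-Waterman DP, exhaustive ATG-scan uORF enumeration, the
clipped-window identity average, and codon-difference counting by
explicit pathway enumeration.
"""

from __future__ import annotations

import itertools
from typing import NamedTuple

GAP_CHARS = {"-"}
STOPS = {"TAA", "TAG", "TGA"}

_GENETIC_CODE = {}
_bases = "TCAG"
_aas = "FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG"
for _i, (_a, _b, _c) in enumerate(itertools.product(_bases, repeat=3)):
    _GENETIC_CODE[_a + _b + _c] = _aas[_i]


def gotoh_global_score(q: str, r: str, match: int, mismatch: int, gap_open: int, gap_extend: int) -> float:
    """Optimal global affine-gap alignment score by three-matrix DP.

    A gap run of length L costs gap_open + gap_extend * (L - 1); end
    gaps are penalised like internal gaps; N never matches anything.
    """
    NEG = float("-inf")
    n, m = len(q), len(r)

    def s(a: str, b: str) -> int:
        return match if (a == b and a != "N") else mismatch

    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    X = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in query (consumes r)
    Y = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in reference (consumes q)
    M[0][0] = 0.0
    for j in range(1, m + 1):
        X[0][j] = -gap_open - gap_extend * (j - 1)
    for i in range(1, n + 1):
        Y[i][0] = -gap_open - gap_extend * (i - 1)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            M[i][j] = max(M[i - 1][j - 1], X[i - 1][j - 1], Y[i - 1][j - 1]) + s(q[i - 1], r[j - 1])
            X[i][j] = max(M[i][j - 1] - gap_open, X[i][j - 1] - gap_extend, Y[i][j - 1] - gap_open)
            Y[i][j] = max(M[i - 1][j] - gap_open, Y[i - 1][j] - gap_extend, X[i - 1][j] - gap_open)
    return max(M[n][m], X[n][m], Y[n][m])


def smith_waterman_score(q: str, r: str, matrix, gap_first: int = 12, gap_next: int = 1) -> float:
    """Optimal local alignment score; gap run of length L costs
    gap_first + gap_next * (L - 1)."""
    n, m = len(q), len(r)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]
    F = [[NEG] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(H[i][j - 1] - gap_first, E[i][j - 1] - gap_next)
            F[i][j] = max(H[i - 1][j] - gap_first, F[i - 1][j] - gap_next)
            H[i][j] = max(
                0.0,
                H[i - 1][j - 1] + matrix[q[i - 1], r[j - 1]],
                E[i][j],
                F[i][j],
            )
            best = max(best, H[i][j])
    return best


class OracleUorf(NamedTuple):
    start: int
    end: int
    overlap_nt: int
    peptide: str


def translate(seq: str) -> str:
    return "".join(_GENETIC_CODE.get(seq[i : i + 3], "X") for i in range(0, len(seq) - 2, 3))


def enumerate_uorfs(
    seq: str,
    morf_start: int,
    min_len_codons: int,
    max_overlap_nt: int,
    search_limit_nt: int | None,
) -> list[OracleUorf]:
    """Exhaustive ATG scan: every upstream AUG extended codon by codon
    to its first stop, then filtered exactly as specified."""
    out = []
    limit = morf_start if search_limit_nt is None else min(morf_start, search_limit_nt)
    for a in range(limit):
        if seq[a : a + 3] != "ATG":
            continue
        stop_end = None
        i = a
        while i + 3 <= len(seq):
            if seq[i : i + 3] in STOPS:
                stop_end = i + 3
                break
            i += 3
        if stop_end is None:
            continue
        overlap = max(0, stop_end - morf_start)
        n_codons = (stop_end - a) // 3 - 1
        if overlap > max_overlap_nt or n_codons < min_len_codons:
            continue
        out.append(OracleUorf(a, stop_end, overlap, translate(seq[a : stop_end - 3])))
    return out


def clipped_window_profile(q_aligned: str, match_seq, w: int) -> list[float]:
    """Identity profile by direct clipped-window averaging.

    For each non-gap query column i (1-based), average M over the
    window [i - z, i + z] clipped to [1, m].
    """
    m = len(q_aligned)
    z = w // 2
    out = []
    for i in range(1, m + 1):
        if q_aligned[i - 1] in GAP_CHARS:
            continue
        lo, hi = max(1, i - z), min(m, i + z)
        vals = match_seq[lo - 1 : hi]
        out.append(float(sum(vals)) / (hi - lo + 1))
    return out


def pathway_differences(c1: str, c2: str) -> tuple[float, float]:
    """(syn, nonsyn) difference counts averaged over all stop-free
    mutational pathways between two sense codons."""
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return 0.0, 0.0
    totals = []
    for order in itertools.permutations(diff):
        cur = c1
        sd = nd = 0
        ok = True
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOPS:
                ok = False
                break
            if _GENETIC_CODE[nxt] == _GENETIC_CODE[cur]:
                sd += 1
            else:
                nd += 1
            cur = nxt
        if ok:
            totals.append((sd, nd))
    if not totals:
        return float("nan"), float("nan")
    return (
        sum(t[0] for t in totals) / len(totals),
        sum(t[1] for t in totals) / len(totals),
    )
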