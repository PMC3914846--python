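"""Synonymous/non-synonymous substitution rate estimation (Ka/Ks).

Two counting estimators over a gap- and stop-free codon alignment:

NG86 (Nei & Gojobori 1986)
    Equal-weight site counting: each codon position contributes the
    fraction of its three possible changes that are synonymous
    (changes to stop codons count as non-synonymous, so S + N = 3L).
    Differences between codons differing at several positions are
    averaged over all mutational pathways that avoid stop codons.
    Proportions pS = Sd/S and pN = Nd/N are corrected for multiple
    hits with the Jukes–Cantor formula.

YN00 (after Yang & Nielsen 2000)
    Site counting weighted by the transition/transversion ratio kappa
    and F3x4 position-specific nucleotide frequencies, so a transition
    opportunity counts kappa times a transversion opportunity.
    Differences are pathway-averaged as in NG86 but split into
    transitions and transversions within the synonymous and
    non-synonymous classes, and each class is corrected with the
    Kimura two-parameter formula. Kappa is estimated beforehand from
    fourfold-degenerate and nondegenerate sites via K80 — at those
    sites the ts/tv ratio is undistorted by the genetic code, unlike
    the ratio among synonymous differences, which confounds kappa with
    code structure. If no degenerate site yields an estimate, kappa
    falls back to 2 and the result is flagged.

A Ka/Ks ratio below 1 indicates purifying selection on the encoded
peptide; the mORF's ratio serves as an internal control against which
a uORF's ratio can be judged. Standard genetic code only.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from Bio.Data import CodonTable

from .align import AlignmentResult, ScoringParams, global_align
from .errors import InsufficientDataError, ParameterError
from .model import OrfInterval, Transcript, UorfRecord
from .uorfs import find_morf

__all__ = [
    "CodonAlignment",
    "KaKsResult",
    "PairedKaKsReport",
    "codon_align",
    "estimate_kaks",
    "compare_uorf_morf",
    "SENSE_CODONS",
]

_TABLE = CodonTable.unambiguous_dna_by_id[1]
_NT = "TCAG"
STOP_CODONS = frozenset(_TABLE.stop_codons)
SENSE_CODONS: tuple[str, ...] = tuple(
    c for c in ("".join(t) for t in itertools.product(_NT, repeat=3)) if c not in STOP_CODONS
)
_AA = {c: _TABLE.forward_table[c] for c in SENSE_CODONS}
_CODON_INDEX = {c: k for k, c in enumerate(SENSE_CODONS)}

_PURINES = frozenset("AG")


def _is_transition(a: str, b: str) -> bool:
    return a != b and ((a in _PURINES) == (b in _PURINES))


# ---------------------------------------------------------------------------
# Static per-codon change tables (built once at import).
# For every sense codon: the 9 single-nucleotide changes, each with its
# position, target nucleotide, transition flag, and classification
# (synonymous / non-synonymous / to-stop).
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class _Change:
    pos: int
    target_nt: str
    is_ts: bool
    to_stop: bool
    is_syn: bool


def _changes(codon: str) -> tuple[_Change, ...]:
    out = []
    for pos in range(3):
        for nt in _NT:
            if nt == codon[pos]:
                continue
            alt = codon[:pos] + nt + codon[pos + 1 :]
            to_stop = alt in STOP_CODONS
            out.append(
                _Change(
                    pos=pos,
                    target_nt=nt,
                    is_ts=_is_transition(codon[pos], nt),
                    to_stop=to_stop,
                    is_syn=(not to_stop) and _AA[alt] == _AA[codon],
                )
            )
    return tuple(out)


_CHANGES: dict[str, tuple[_Change, ...]] = {c: _changes(c) for c in SENSE_CODONS}

#: NG86 synonymous sites per codon (changes to stops are non-synonymous).
_NG86_S: dict[str, float] = {
    c: sum(ch.is_syn for ch in _CHANGES[c]) / 3.0 for c in SENSE_CODONS
}


@lru_cache(maxsize=None)
def _pathway_counts(c1: str, c2: str) -> tuple[float, float, float, float, float, float]:
    """Pathway-averaged difference counts between two sense codons.

    Returns (sd, nd, sd_ts, sd_tv, nd_ts, nd_tv). Pathways passing
    through a stop codon are excluded from the average (if every
    pathway does, all are used as a fallback — this cannot occur for
    codon pairs differing at <= 2 positions under the standard code).
    """
    diff = [k for k in range(3) if c1[k] != c2[k]]
    if not diff:
        return (0.0, 0.0, 0.0, 0.0, 0.0, 0.0)

    def walk(order: tuple[int, ...]) -> tuple[float, ...] | None:
        cur = c1
        sd = nd = sd_ts = sd_tv = nd_ts = nd_tv = 0.0
        for pos in order:
            nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
            if nxt in STOP_CODONS:
                return None
            ts = _is_transition(cur[pos], c2[pos])
            if _AA[nxt] == _AA[cur]:
                sd += 1
                sd_ts += ts
                sd_tv += not ts
            else:
                nd += 1
                nd_ts += ts
                nd_tv += not ts
            cur = nxt
        return (sd, nd, sd_ts, sd_tv, nd_ts, nd_tv)

    results = [r for r in (walk(o) for o in itertools.permutations(diff)) if r is not None]
    if not results:
        results = []
        for order in itertools.permutations(diff):
            cur = c1
            sd = nd = sd_ts = sd_tv = nd_ts = nd_tv = 0.0
            for pos in order:
                nxt = cur[:pos] + c2[pos] + cur[pos + 1 :]
                ts = _is_transition(cur[pos], c2[pos])
                syn = nxt not in STOP_CODONS and cur not in STOP_CODONS and (
                    nxt in _AA and cur in _AA and _AA[nxt] == _AA[cur]
                )
                if syn:
                    sd += 1
                    sd_ts += ts
                    sd_tv += not ts
                else:
                    nd += 1
                    nd_ts += ts
                    nd_tv += not ts
                cur = nxt
            results.append((sd, nd, sd_ts, sd_tv, nd_ts, nd_tv))
    arr = np.asarray(results, dtype=float)
    return tuple(arr.mean(axis=0))


# ---------------------------------------------------------------------------
# Codon alignment extraction
# ---------------------------------------------------------------------------

@dataclass
class CodonAlignment:
    """Gap- and stop-free codon columns extracted from an alignment."""

    codon_pairs: list[tuple[str, str]]
    dropped_codons: int

    @property
    def n_codons(self) -> int:
        return len(self.codon_pairs)


def codon_align(a: AlignmentResult, q_orf: OrfInterval, r_orf: OrfInterval) -> CodonAlignment:
    """Extract paired codons for an ORF from a nucleotide alignment.

    The query frame defines the codon columns: the ORF region of the
    (ungapped) query is walked in codon steps, and each query codon is
    paired with the reference nucleotides aligned to exactly those
    three columns. A codon column is dropped (and counted) when the
    three columns are interrupted by a gap in either sequence, or when
    either triplet contains N or is a stop codon. A terminal query
    stop codon is excluded silently rather than counted as a drop.
    ``r_orf`` is validated but the pairing itself is driven by the
    alignment. Raises :class:`InsufficientDataError` when no clean
    codon column remains.
    """
    query = a.query
    if q_orf.end > len(query):
        raise ParameterError(f"query ORF {q_orf} exceeds query length {len(query)}")
    if r_orf.end > len(a.reference):
        raise ParameterError(f"reference ORF {r_orf} exceeds reference length")
    # Map each ungapped query position to its alignment column.
    q_cols = np.flatnonzero(np.frombuffer(a.q_aligned.encode(), dtype="S1") != b"-")
    end = q_orf.end
    if query[q_orf.end - 3 : q_orf.end] in STOP_CODONS:
        end -= 3
    pairs: list[tuple[str, str]] = []
    dropped = 0
    for qpos in range(q_orf.start, end - 2, 3):
        cols = q_cols[qpos : qpos + 3]
        qc = query[qpos : qpos + 3]
        if cols[2] != cols[0] + 2:  # reference insertion splits the codon
            dropped += 1
            continue
        rc = a.r_aligned[cols[0] : cols[0] + 3]
        if "-" in rc or "N" in rc or "N" in qc:
            dropped += 1
            continue
        if qc in STOP_CODONS or rc in STOP_CODONS:
            dropped += 1
            continue
        pairs.append((qc, rc))
    if not pairs:
        raise InsufficientDataError(
            f"no clean codon columns in ORF {q_orf} ({dropped} dropped)"
        )
    return CodonAlignment(codon_pairs=pairs, dropped_codons=dropped)


# ---------------------------------------------------------------------------
# Estimators
# ---------------------------------------------------------------------------

@dataclass
class KaKsResult:
    """Site and difference counts plus corrected rates for one ORF pair."""

    S: float
    N: float
    Sd: float
    Nd: float
    Ka: float
    Ks: float
    ratio: float | None
    kappa: float | None
    method: str
    flags: tuple[str, ...] = ()

    @property
    def undefined(self) -> bool:
        return self.ratio is None


def _jukes_cantor(p: float) -> tuple[float, bool]:
    """JC69 distance; returns (d, saturated)."""
    if p <= 0.0:
        return 0.0, False
    if p >= 0.75:
        return math.nan, True
    return -0.75 * math.log1p(-4.0 * p / 3.0), False


def _k80(P: float, Q: float) -> tuple[float, float | None, bool]:
    """Kimura two-parameter distance from transition/transversion
    proportions. Returns (d, kappa_or_None, saturated)."""
    if P <= 0.0 and Q <= 0.0:
        return 0.0, None, False
    a1 = 1.0 - 2.0 * P - Q
    a2 = 1.0 - 2.0 * Q
    if a1 <= 0.0 or a2 <= 0.0:
        return math.nan, None, True
    alpha = -0.5 * math.log(a1) + 0.25 * math.log(a2)
    beta = -0.25 * math.log(a2)
    d = alpha + 2.0 * beta
    kappa = alpha / beta if beta > 1e-12 else None
    return d, kappa, False


def _ratio(ka: float, ks: float) -> tuple[float | None, list[str]]:
    flags: list[str] = []
    if math.isnan(ka):
        flags.append("saturated_ka")
    if math.isnan(ks):
        flags.append("saturated_ks")
    if flags:
        return None, flags
    if ks <= 0.0:
        return None, ["undefined_ratio"]
    return ka / ks, []


def _estimate_ng86(c: CodonAlignment) -> KaKsResult:
    L = c.n_codons
    s1 = sum(_NG86_S[q] for q, _ in c.codon_pairs)
    s2 = sum(_NG86_S[r] for _, r in c.codon_pairs)
    S = 0.5 * (s1 + s2)
    N = 3.0 * L - S
    Sd = Nd = 0.0
    for qc, rc in c.codon_pairs:
        sd, nd, *_ = _pathway_counts(qc, rc)
        Sd += sd
        Nd += nd
    pS = Sd / S if S > 0 else 0.0
    pN = Nd / N if N > 0 else 0.0
    Ks, sat_s = _jukes_cantor(pS)
    Ka, sat_n = _jukes_cantor(pN)
    ratio, flags = _ratio(Ka, Ks)
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, Ka=Ka, Ks=Ks, ratio=ratio,
        kappa=None, method="NG86", flags=tuple(flags),
    )


def _f3x4(codon_pairs: list[tuple[str, str]]) -> np.ndarray:
    """Position-specific nucleotide frequencies (3 x 4, order TCAG)."""
    counts = np.zeros((3, 4), dtype=float)
    idx = {nt: k for k, nt in enumerate(_NT)}
    for qc, rc in codon_pairs:
        for codon in (qc, rc):
            for pos in range(3):
                counts[pos, idx[codon[pos]]] += 1.0
    counts += 0.25  # small prior keeps every frequency positive
    return counts / counts.sum(axis=1, keepdims=True)


def _yn00_sites(codon_counts: np.ndarray, freqs: np.ndarray, kappa: float) -> tuple[float, float]:
    """Mean synonymous/non-synonymous sites per codon, kappa- and
    frequency-weighted, normalised so S + N = 3 per codon."""
    idx = {nt: k for k, nt in enumerate(_NT)}
    total = codon_counts.sum()
    S_mean = 0.0
    for ci, codon in enumerate(SENSE_CODONS):
        if codon_counts[ci] == 0:
            continue
        w_syn = w_tot = 0.0
        for ch in _CHANGES[codon]:
            if ch.to_stop:
                continue
            w = (kappa if ch.is_ts else 1.0) * freqs[ch.pos, idx[ch.target_nt]]
            w_tot += w
            if ch.is_syn:
                w_syn += w
        if w_tot > 0:
            S_mean += codon_counts[ci] * 3.0 * w_syn / w_tot
    S_mean /= total
    return S_mean, 3.0 - S_mean


def _degeneracy(codon: str, pos: int) -> int:
    """0 if no change at ``pos`` is synonymous, 4 if all three are,
    2 otherwise."""
    n_syn = sum(ch.is_syn for ch in _CHANGES[codon] if ch.pos == pos)
    return {0: 0, 3: 4}.get(n_syn, 2)


def _estimate_kappa(codon_pairs: list[tuple[str, str]]) -> tuple[float | None, bool]:
    """Kappa from fourfold-degenerate and nondegenerate sites.

    Only sites whose degeneracy class agrees between the two codons
    enter; within each class the ts/tv ratio is undistorted by the
    genetic code, so a K80 fit estimates kappa directly. The two class
    estimates are combined weighted by site count. Returns
    ``(kappa or None, saturated)``.
    """
    counts = {0: [0.0, 0.0, 0.0], 4: [0.0, 0.0, 0.0]}  # class -> [sites, ts, tv]
    for qc, rc in codon_pairs:
        for pos in range(3):
            deg = _degeneracy(qc, pos)
            if deg not in (0, 4) or _degeneracy(rc, pos) != deg:
                continue
            counts[deg][0] += 1.0
            if qc[pos] != rc[pos]:
                if _is_transition(qc[pos], rc[pos]):
                    counts[deg][1] += 1.0
                else:
                    counts[deg][2] += 1.0
    num = den = 0.0
    saturated = False
    for sites, ts, tv in counts.values():
        if sites < 1:
            continue
        _, k, sat = _k80(ts / sites, tv / sites)
        saturated = saturated or sat
        if k is not None:
            num += sites * min(k, 99.0)
            den += sites
    return (num / den if den > 0 else None), saturated


def _estimate_yn00(c: CodonAlignment) -> KaKsResult:
    L = c.n_codons
    codon_counts = np.zeros(len(SENSE_CODONS), dtype=float)
    for qc, rc in c.codon_pairs:
        codon_counts[_CODON_INDEX[qc]] += 1.0
        codon_counts[_CODON_INDEX[rc]] += 1.0
    freqs = _f3x4(c.codon_pairs)

    Sd = Nd = Sd_ts = Sd_tv = Nd_ts = Nd_tv = 0.0
    for qc, rc in c.codon_pairs:
        sd, nd, sdts, sdtv, ndts, ndtv = _pathway_counts(qc, rc)
        Sd += sd
        Nd += nd
        Sd_ts += sdts
        Sd_tv += sdtv
        Nd_ts += ndts
        Nd_tv += ndtv

    kappa_hat, kappa_sat = _estimate_kappa(c.codon_pairs)
    kappa = kappa_hat if kappa_hat is not None else 2.0
    kappa = min(max(kappa, 0.01), 99.0)
    s_per, n_per = _yn00_sites(codon_counts, freqs, kappa)
    S, N = s_per * L, n_per * L
    dS, _, sat_s = _k80(Sd_ts / S if S > 0 else 0.0, Sd_tv / S if S > 0 else 0.0)
    dN, _, sat_n = _k80(Nd_ts / N if N > 0 else 0.0, Nd_tv / N if N > 0 else 0.0)
    flags = (["saturated_ks"] if sat_s else []) + (["saturated_ka"] if sat_n else [])
    if kappa_hat is None:
        flags.append("kappa_default")
    if kappa_sat:
        flags.append("kappa_saturated_sites")
    ratio, rflags = _ratio(dN, dS)
    for f in rflags:
        if f not in flags:
            flags.append(f)
    return KaKsResult(
        S=S, N=N, Sd=Sd, Nd=Nd, Ka=dN, Ks=dS, ratio=ratio,
        kappa=kappa, method="YN00", flags=tuple(flags),
    )


def estimate_kaks(c: CodonAlignment, method: str = "YN00") -> KaKsResult:
    """Estimate Ka, Ks and their ratio for a codon alignment.

    ``method`` is ``"NG86"`` or ``"YN00"`` (case-insensitive).
    Saturation (a divergence too large for the distance correction) is
    reported via result flags, not an exception; an undefined ratio
    (Ks = 0) likewise.
    """
    if c.n_codons < 1:
        raise InsufficientDataError("codon alignment is empty")
    m = method.upper()
    if m == "NG86":
        return _estimate_ng86(c)
    if m == "YN00":
        return _estimate_yn00(c)
    raise ParameterError(f"unknown method {method!r} (expected NG86 or YN00)")


# ---------------------------------------------------------------------------
# uORF vs mORF comparison
# ---------------------------------------------------------------------------

@dataclass
class PairedKaKsReport:
    """Ka/Ks for a uORF and the mORF internal control of one pair."""

    uorf: KaKsResult | None
    morf: KaKsResult | None
    uorf_error: str | None = None
    morf_error: str | None = None

    @property
    def ratio_of_ratios(self) -> float | None:
        """uORF (Ka/Ks) divided by mORF (Ka/Ks); None when either side
        is missing or undefined."""
        if self.uorf is None or self.morf is None:
            return None
        if self.uorf.ratio is None or self.morf.ratio is None or self.morf.ratio == 0:
            return None
        return self.uorf.ratio / self.morf.ratio


def compare_uorf_morf(
    query: Transcript,
    ref: Transcript,
    uorf_pair: tuple[UorfRecord, UorfRecord],
    method: str = "YN00",
    scoring: ScoringParams | None = None,
    alignment: AlignmentResult | None = None,
) -> PairedKaKsReport:
    """Estimate Ka/Ks for a uORF pair and for the mORF internal control.

    The transcripts are globally aligned once (unless ``alignment`` is
    supplied); codon alignments for the uORF (query/reference intervals
    from ``uorf_pair``) and for the two mORFs are extracted from it. A
    side with too few clean codons is flagged in the report rather than
    aborting the other side.
    """
    if alignment is None:
        alignment = global_align(query.sequence, ref.sequence, scoring)
    qu, ru = uorf_pair
    results: dict[str, KaKsResult | None] = {}
    errors: dict[str, str | None] = {"uORF": None, "mORF": None}
    regions: dict[str, tuple[OrfInterval, OrfInterval] | None] = {
        "uORF": (qu.interval, ru.interval)
    }
    try:
        regions["mORF"] = (find_morf(query), find_morf(ref))
    except Exception as exc:
        regions["mORF"] = None
        errors["mORF"] = str(exc)
    for name, ivs in regions.items():
        if ivs is None:
            results[name] = None
            continue
        try:
            results[name] = estimate_kaks(codon_align(alignment, *ivs), method)
        except (InsufficientDataError, ParameterError) as exc:
            results[name] = None
            errors[name] = str(exc)
    return PairedKaKsReport(
        uorf=results["uORF"],
        morf=results["mORF"],
        uorf_error=errors["uORF"],
        morf_error=errors["mORF"],
    )
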