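"""Locating the main ORF and upstream ORFs on a transcript.

A uORF here is an AUG-initiated open reading frame whose start codon
lies strictly 5' of the main ORF start. Candidates must be closed by an
in-frame stop codon within the transcript; the stop may extend at most
``max_overlap_nt`` nucleotides into the main CDS. Only AUG starts are
recognised; near-cognate starts (CUG/GUG) are out of scope.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass

from Bio.Seq import Seq

from .errors import NoMorfError, ParameterError
from .model import STOP_CODONS, OrfInterval, Transcript, UorfRecord

__all__ = ["UorfSearchParams", "find_morf", "find_uorfs", "translate_codons"]


@dataclass(frozen=True)
class UorfSearchParams:
    """User-tunable uORF search parameters.

    min_len_codons
        Minimum number of coding codons (stop excluded). Default 10:
        the shortest peptide for which conservation statistics are
        plausibly informative.
    max_overlap_nt
        How far (nt) the uORF, stop codon included, may extend 3' of
        the mORF start. Default 0: uORFs entirely within the 5'UTR.
    search_limit_nt
        If set, only uAUGs starting within the first N nucleotides of
        the transcript are considered.
    """

    min_len_codons: int = 10
    max_overlap_nt: int = 0
    search_limit_nt: int | None = None

    def __post_init__(self) -> None:
        if self.min_len_codons < 1:
            raise ParameterError("min_len_codons must be >= 1")
        if self.max_overlap_nt < 0:
            raise ParameterError("max_overlap_nt must be >= 0")
        if self.search_limit_nt is not None and self.search_limit_nt < 0:
            raise ParameterError("search_limit_nt must be >= 0")


def translate_codons(seq: str) -> str:
    """Translate an in-frame coding region (standard code, no stop)."""
    return str(Seq(seq).translate(table=1))


def _stop_positions_by_frame(seq: str) -> list[list[int]]:
    """Sorted start positions of stop codons, per reading frame."""
    stops: list[list[int]] = [[], [], []]
    for i in range(len(seq) - 2):
        if seq[i : i + 3] in STOP_CODONS:
            stops[i % 3].append(i)
    return stops


def _next_inframe_stop(stops: list[list[int]], pos: int) -> int | None:
    """Position of the first in-frame stop codon at or after ``pos``."""
    frame_stops = stops[pos % 3]
    k = bisect.bisect_left(frame_stops, pos)
    return frame_stops[k] if k < len(frame_stops) else None


def find_morf(t: Transcript) -> OrfInterval:
    """Locate the main ORF (mORF) of a transcript.

    An annotated CDS takes precedence. Otherwise the longest
    AUG-initiated, stop-terminated ORF across the three forward frames
    is returned, ties broken by the 5'-most start. Raises
    :class:`NoMorfError` when no complete ORF exists — such records are
    unusable, mirroring the database-build exclusion rule.
    """
    if t.cds is not None:
        return t.cds
    seq = t.sequence
    stops = _stop_positions_by_frame(seq)
    best: OrfInterval | None = None
    pos = seq.find("ATG")
    while pos != -1:
        stop = _next_inframe_stop(stops, pos)
        if stop is not None:
            cand = OrfInterval(pos, stop + 3)
            if best is None or len(cand) > len(best):
                best = cand
        pos = seq.find("ATG", pos + 1)
    if best is None:
        raise NoMorfError(f"{t.accession}: no AUG-initiated, stop-terminated ORF")
    return best


def find_uorfs(t: Transcript, p: UorfSearchParams | None = None) -> list[UorfRecord]:
    """Locate all qualifying uORFs on a transcript.

    Every AUG strictly 5' of the mORF start is extended in frame to its
    first stop codon. Candidates are kept when the stop exists within
    the transcript, the overlap into the CDS does not exceed
    ``max_overlap_nt``, and the coding length reaches
    ``min_len_codons``. Nested uORFs are reported independently.
    Output is sorted by start position.
    """
    if p is None:
        p = UorfSearchParams()
    morf = find_morf(t)
    seq = t.sequence
    stops = _stop_positions_by_frame(seq)
    limit = morf.start
    if p.search_limit_nt is not None:
        limit = min(limit, p.search_limit_nt)
    out: list[UorfRecord] = []
    pos = seq.find("ATG")
    while pos != -1 and pos < limit:
        stop = _next_inframe_stop(stops, pos)
        if stop is not None:
            end = stop + 3
            overlap = max(0, end - morf.start)
            n_coding = (end - pos) // 3 - 1
            if overlap <= p.max_overlap_nt and n_coding >= p.min_len_codons:
                out.append(
                    UorfRecord(
                        parent_accession=t.accession,
                        interval=OrfInterval(pos, end),
                        peptide=translate_codons(seq[pos:stop]),
                        overlap_nt=overlap,
                        terminated=True,
                    )
                )
        pos = seq.find("ATG", pos + 1)
    return out
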