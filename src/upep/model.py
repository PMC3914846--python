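"""Core domain types: transcripts, ORF intervals and located uORFs.

Coordinate convention: all intervals are 0-based half-open internally.
User-facing reports (TSV, CLI) convert to 1-based inclusive, the style
used by GenBank/RefSeq feature tables. ORF intervals span the start codon
through the stop codon inclusive, so a complete ORF has a length that is
a multiple of three and encodes ``(length / 3) - 1`` amino acids.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import FormatError

VALID_NT = frozenset("ACGTN")

#: Stop codons of the standard genetic code.
STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})


def normalize_sequence(raw: str, *, context: str = "sequence") -> str:
    """Upper-case a nucleotide string and map RNA U to DNA T.

    Raises :class:`FormatError` if any character outside {A,C,G,T,N}
    survives normalisation. ``context`` names the offending record in the
    error message.
    """
    seq = raw.upper().replace("U", "T")
    bad = set(seq) - VALID_NT
    if bad:
        raise FormatError(
            f"{context}: illegal nucleotide character(s) {sorted(bad)!r}"
        )
    return seq


@dataclass(frozen=True, order=True)
class OrfInterval:
    """Half-open span ``[start, end)`` of an ORF on a transcript.

    ``frame`` is the reading frame relative to the transcript 5' end,
    derived as ``start % 3``.
    """

    start: int
    end: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")

    @property
    def frame(self) -> int:
        return self.start % 3

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def n_codons(self) -> int:
        """Number of codons spanned, including the stop codon."""
        return (self.end - self.start) // 3

    def as_one_based(self) -> tuple[int, int]:
        """(start, end) in 1-based inclusive display coordinates."""
        return self.start + 1, self.end


@dataclass
class Transcript:
    """A sense-strand mRNA sequence with optional annotated CDS.

    ``morf_start_undefined`` marks records whose CDS start is missing or
    fuzzy in the source annotation (e.g. a GenBank ``<1..200`` location);
    the database builder excludes such records.
    """

    accession: str
    sequence: str
    cds: OrfInterval | None = None
    species: str | None = None
    morf_start_undefined: bool = False

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"{self.accession}: empty sequence")
        if self.cds is not None:
            if self.cds.end > len(self.sequence):
                raise ValueError(
                    f"{self.accession}: CDS {self.cds} exceeds sequence length"
                )
            if len(self.cds) % 3 != 0:
                raise ValueError(
                    f"{self.accession}: CDS length {len(self.cds)} not a multiple of 3"
                )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class UorfRecord:
    """A located upstream ORF and the peptide it encodes.

    ``overlap_nt`` is the number of nucleotides by which the uORF
    (including its stop codon) extends 3' of the main ORF start;
    ``terminated`` records whether an in-frame stop codon closes the
    uORF within the transcript.
    """

    parent_accession: str
    interval: OrfInterval
    peptide: str
    overlap_nt: int = 0
    terminated: bool = True

    @property
    def length_codons(self) -> int:
        """Coding codons, excluding the stop codon."""
        return self.interval.n_codons - (1 if self.terminated else 0)
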