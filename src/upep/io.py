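"""FASTA and GenBank ingestion built on Bio.SeqIO.

Both readers normalise sequences (upper-case, U→T) and return
:class:`~upep.model.Transcript` objects. The GenBank reader additionally
lifts the first CDS feature into the transcript's ``cds`` interval and
flags records whose CDS start is unannotated or fuzzy, so the database
builder can apply its exclusion rule.
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Iterable

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import BeforePosition, ExactPosition, UnknownPosition
from Bio.SeqRecord import SeqRecord

from .errors import EmptyInputError, FormatError
from .model import OrfInterval, Transcript, normalize_sequence

logger = logging.getLogger(__name__)

__all__ = ["read_fasta", "read_genbank", "write_fasta", "write_genbank"]


def read_fasta(path: str | Path) -> list[Transcript]:
    """Read a (multi-record) FASTA file of mRNA sequences.

    Sequences are normalised; no CDS annotation is attached. Raises
    :class:`FormatError` naming the offending record on illegal
    characters, and :class:`EmptyInputError` on a record-less file.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: record {rec.id!r} has no sequence")
        seq = normalize_sequence(str(rec.seq), context=f"record {rec.id!r}")
        transcripts.append(Transcript(accession=rec.id, sequence=seq))
    if not transcripts:
        raise EmptyInputError(f"{path}: no FASTA records found")
    return transcripts


def write_fasta(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts to FASTA (accession as the header id)."""
    records = [
        SeqRecord(Seq(t.sequence), id=t.accession, description="")
        for t in transcripts
    ]
    SeqIO.write(records, str(path), "fasta")


def write_genbank(transcripts: Iterable[Transcript], path: str | Path) -> None:
    """Write transcripts as GenBank flat records with a CDS feature.

    A transcript flagged ``morf_start_undefined`` (or without a CDS) is
    emitted with a fuzzy ``<1..n`` CDS location, emulating RefSeq
    records whose mORF start is not defined.
    """
    from Bio.SeqFeature import SeqFeature, SimpleLocation

    records = []
    for t in transcripts:
        rec = SeqRecord(Seq(t.sequence), id=t.accession, name=t.accession.split(".")[0][:16],
                        description="synthetic mRNA")
        rec.annotations["molecule_type"] = "mRNA"
        if t.species:
            rec.annotations["organism"] = t.species
        if t.cds is not None and not t.morf_start_undefined:
            loc = SimpleLocation(t.cds.start, t.cds.end, strand=1)
        else:
            end = min(len(t.sequence), 300)
            end -= end % 3
            loc = SimpleLocation(BeforePosition(0), end or 3, strand=1)
        rec.features.append(SeqFeature(loc, type="CDS"))
        records.append(rec)
    SeqIO.write(records, str(path), "genbank")


def _cds_interval(feature, seq_len: int) -> tuple[OrfInterval | None, bool]:
    """Convert a CDS feature location to a half-open interval.

    Returns ``(interval, start_undefined)``. Fuzzy or unknown start
    positions (``<1..200`` style) leave the interval unset and flag the
    record, mirroring the exclusion applied when building uORF databases.
    """
    loc = feature.location
    if loc is None:
        return None, True
    start, end = loc.start, loc.end
    if isinstance(start, (BeforePosition, UnknownPosition)) or not isinstance(
        start, ExactPosition
    ):
        return None, True
    start_i, end_i = int(start), int(end)
    if not (0 <= start_i < end_i <= seq_len) or (end_i - start_i) % 3 != 0:
        # Joined/partial CDS spans that do not form a clean in-frame
        # interval on the mRNA are treated as undefined.
        return None, True
    return OrfInterval(start_i, end_i), False


def read_genbank(path: str | Path) -> list[Transcript]:
    """Read a GenBank flat file of mRNA records.

    The first CDS feature supplies the annotated mORF interval
    (GenBank 1-based inclusive ``a..b`` becomes half-open ``[a-1, b)``).
    Records with no CDS, or with a fuzzy/undefined CDS start, are
    returned with ``morf_start_undefined=True``. Records without
    sequence are skipped with a warning.
    """
    path = Path(path)
    transcripts: list[Transcript] = []
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except ValueError as exc:
        raise FormatError(f"{path}: unparsable GenBank file: {exc}") from exc
    for rec in records:
        try:
            raw = str(rec.seq)
        except Exception:  # undefined sequence (CONTIG-only record)
            raw = ""
        if not raw:
            logger.warning("%s: record %s has no sequence, skipped", path, rec.id)
            continue
        try:
            seq = normalize_sequence(raw, context=f"record {rec.id!r}")
        except FormatError:
            raise
        cds_features = [f for f in rec.features if f.type == "CDS"]
        species = rec.annotations.get("organism")
        if not cds_features:
            transcripts.append(
                Transcript(rec.id, seq, species=species, morf_start_undefined=True)
            )
            continue
        interval, undefined = _cds_interval(cds_features[0], len(seq))
        transcripts.append(
            Transcript(
                rec.id,
                seq,
                cds=interval,
                species=species,
                morf_start_undefined=undefined,
            )
        )
    if not transcripts:
        raise EmptyInputError(f"{path}: no usable GenBank records found")
    return transcripts
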