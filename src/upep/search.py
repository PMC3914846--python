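"""uORF database construction and conserved-uPEP search.

The database holds the uORF peptides extracted from a reference
transcript set; transcripts whose mORF start is undefined (or on which
no mORF can be located) are excluded and counted, so a database never
contains a uORF from an unusable record.

Conservation search is peptide-level: each query uORF peptide is
locally aligned (Smith–Waterman, BLOSUM62, affine gaps 11/1) against
every database peptide, which preferences uPEPs conserved at the amino
acid level over mere nucleotide-level uORF conservation. Hits at or
above the raw-score threshold are reported best-first, each carrying
the reference transcript pairing the heatmap stage needs. A
Karlin–Altschul style expectation (database-size aware) is attached to
every hit as a significance guide.
"""

from __future__ import annotations

import hashlib
import json
import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .errors import EmptyDatabaseError, FormatError
from .model import OrfInterval, Transcript, UorfRecord
from .uorfs import UorfSearchParams, find_uorfs

logger = logging.getLogger(__name__)

__all__ = [
    "UorfDatabase",
    "SearchHit",
    "build_uorf_db",
    "search_conserved",
    "save_db",
    "load_db",
    "DEFAULT_MIN_SCORE",
]

#: Default raw-score reporting threshold, calibrated so that random
#: 15-residue peptides score a hit in <5% of searches against a
#: 10^4-record database of random peptides (see docs/methods.md).
DEFAULT_MIN_SCORE = 40.0

# Gapped Karlin-Altschul parameters for BLOSUM62 with gap costs 11 + k
# (the classic protein-search defaults).
_KA_LAMBDA = 0.267
_KA_K = 0.041


def _peptide_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    # BLAST semantics: a gap of length k costs 11 + k.
    aligner.open_gap_score = -12.0
    aligner.extend_gap_score = -1.0
    return aligner


@dataclass
class UorfDatabase:
    """A built uORF database plus its provenance metadata."""

    records: list[UorfRecord]
    transcripts: dict[str, Transcript]
    source_meta: dict
    version_tag: str

    @property
    def n_residues(self) -> int:
        return sum(len(r.peptide) for r in self.records)

    def __len__(self) -> int:
        return len(self.records)


@dataclass
class SearchHit:
    """One query-uORF / reference-uORF pairing above threshold."""

    query_uorf: UorfRecord
    ref_uorf: UorfRecord
    q_pep_aligned: str
    r_pep_aligned: str
    raw_score: float
    bit_like_score: float
    significance: float

    @property
    def ref_accession(self) -> str:
        return self.ref_uorf.parent_accession


def build_uorf_db(
    transcripts: Sequence[Transcript],
    p: UorfSearchParams | None = None,
    version_tag: str | None = None,
) -> UorfDatabase:
    """Extract uORFs from a reference transcript set into a database.

    Transcripts flagged mORF-start-undefined, and those on which no
    mORF can be located, are excluded and counted in ``source_meta``.
    The build is deterministic: identical input yields an identical
    database (and version tag).
    """
    if p is None:
        p = UorfSearchParams()
    if not transcripts:
        raise EmptyDatabaseError("no input transcripts")
    digest = hashlib.sha256()
    records: list[UorfRecord] = []
    kept: dict[str, Transcript] = {}
    excluded = 0
    for t in transcripts:
        digest.update(t.accession.encode())
        digest.update(t.sequence.encode())
        if t.morf_start_undefined:
            excluded += 1
            continue
        try:
            uorfs = find_uorfs(t, p)
        except Exception:
            excluded += 1
            continue
        kept[t.accession] = t
        records.extend(uorfs)
    if not kept:
        raise EmptyDatabaseError(
            f"no usable transcripts ({excluded} excluded as mORF-undefined)"
        )
    tag = version_tag or digest.hexdigest()[:12]
    meta = {
        "min_len_codons": p.min_len_codons,
        "max_overlap_nt": p.max_overlap_nt,
        "search_limit_nt": p.search_limit_nt,
        "n_input": len(transcripts),
        "n_excluded_morf_undefined": excluded,
        "n_transcripts": len(kept),
        "n_uorfs": len(records),
        "input_digest": digest.hexdigest(),
    }
    return UorfDatabase(records=records, transcripts=kept, source_meta=meta, version_tag=tag)


def search_conserved(
    query: Transcript,
    db: UorfDatabase,
    p: UorfSearchParams | None = None,
    min_score: float = DEFAULT_MIN_SCORE,
) -> list[SearchHit]:
    """Find conserved uPEP candidates for a query transcript.

    Query uORFs are extracted under ``p`` and their peptides aligned
    against every database peptide; pairings scoring at least
    ``min_score`` are returned sorted most-conserved-first (raw score,
    ties broken by reference accession and coordinates for
    determinism). A query without uORFs yields an empty list with a
    logged notice.
    """
    if not db.records:
        raise EmptyDatabaseError("search requires a non-empty database")
    query_uorfs = find_uorfs(query, p)
    if not query_uorfs:
        logger.info("%s: no qualifying uORFs on query; nothing to search", query.accession)
        return []
    aligner = _peptide_aligner()
    db_residues = max(db.n_residues, 1)
    hits: list[SearchHit] = []
    for qu in query_uorfs:
        if not qu.peptide:
            continue
        for ru in db.records:
            if not ru.peptide:
                continue
            score = aligner.score(qu.peptide, ru.peptide)
            if score < min_score:
                continue
            aln = aligner.align(qu.peptide, ru.peptide)[0]
            bits = (_KA_LAMBDA * score - math.log(_KA_K)) / math.log(2.0)
            evalue = len(qu.peptide) * db_residues * math.pow(2.0, -bits)
            hits.append(
                SearchHit(
                    query_uorf=qu,
                    ref_uorf=ru,
                    q_pep_aligned=str(aln[0]),
                    r_pep_aligned=str(aln[1]),
                    raw_score=float(score),
                    bit_like_score=bits,
                    significance=evalue,
                )
            )
    hits.sort(
        key=lambda h: (
            -h.raw_score,
            h.ref_uorf.parent_accession,
            h.ref_uorf.interval.start,
            h.query_uorf.interval.start,
        )
    )
    return hits


def save_db(db: UorfDatabase, out_dir: str | Path) -> Path:
    """Persist a database as a plain-text bundle.

    ``peptides.fasta`` holds one record per uORF peptide with header
    ``parent|start-end|overlap_nt`` (1-based inclusive coordinates);
    ``transcripts.fasta`` keeps the source mRNAs (needed later by the
    heatmap stage); ``meta.json`` records build parameters, the
    exclusion count and the version tag.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "peptides.fasta", "w") as fh:
        for r in db.records:
            s1, e1 = r.interval.as_one_based()
            fh.write(f">{r.parent_accession}|{s1}-{e1}|{r.overlap_nt}\n{r.peptide}\n")
    with open(out_dir / "transcripts.fasta", "w") as fh:
        for t in db.transcripts.values():
            cds = ""
            if t.cds is not None:
                c1, c2 = t.cds.as_one_based()
                cds = f" cds={c1}-{c2}"
            fh.write(f">{t.accession}{cds}\n{t.sequence}\n")
    with open(out_dir / "meta.json", "w") as fh:
        json.dump({"version_tag": db.version_tag, **db.source_meta}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return out_dir


def load_db(db_dir: str | Path) -> UorfDatabase:
    """Load a database bundle written by :func:`save_db`."""
    db_dir = Path(db_dir)
    try:
        meta = json.loads((db_dir / "meta.json").read_text())
    except FileNotFoundError as exc:
        raise FormatError(f"{db_dir}: not a database bundle (meta.json missing)") from exc
    transcripts: dict[str, Transcript] = {}
    from Bio import SeqIO

    for rec in SeqIO.parse(str(db_dir / "transcripts.fasta"), "fasta"):
        cds = None
        for tok in rec.description.split():
            if tok.startswith("cds="):
                a, b = tok[4:].split("-")
                cds = OrfInterval(int(a) - 1, int(b))
        transcripts[rec.id] = Transcript(rec.id, str(rec.seq), cds=cds)
    records: list[UorfRecord] = []
    for rec in SeqIO.parse(str(db_dir / "peptides.fasta"), "fasta"):
        try:
            parent, span, overlap = rec.id.split("|")
            a, b = span.split("-")
        except ValueError as exc:
            raise FormatError(f"{db_dir}: bad peptide header {rec.id!r}") from exc
        records.append(
            UorfRecord(
                parent_accession=parent,
                interval=OrfInterval(int(a) - 1, int(b)),
                peptide=str(rec.seq),
                overlap_nt=int(overlap),
            )
        )
    tag = meta.pop("version_tag", "")
    return UorfDatabase(records=records, transcripts=transcripts, source_meta=meta, version_tag=tag)
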