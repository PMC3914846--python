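"""End-to-end conserved-uPEP analysis runs.

``run_conserved_upep_search`` reproduces the full flow: query uORF
extraction → translated search against a uORF database → per-hit global
mRNA alignment → identity profile(s) and heatmap → uORF and mORF Ka/Ks
— writing a per-hit artefact directory and a summary TSV sorted
most-conserved-first. ``run_heatmap_only`` drives the alignment +
heatmap stages directly on a user-supplied pair. Both are fully
deterministic given inputs and configuration.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .align import ScoringParams, global_align
from .errors import NoMorfError, UpepError
from .kaks import KaKsResult, PairedKaKsReport, compare_uorf_morf
from .model import Transcript
from .profile import (
    DEFAULT_GRADIENT,
    DEFAULT_WINDOW,
    compute_profile,
    reference_profile,
    render_heatmap,
    write_profile_tsv,
)
from .search import DEFAULT_MIN_SCORE, SearchHit, UorfDatabase, search_conserved
from .uorfs import UorfSearchParams, find_morf, find_uorfs

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_conserved_upep_search", "run_heatmap_only"]


@dataclass
class RunConfig:
    """Configuration of a pipeline run (defaults follow the tool's
    standard settings: +5/-4 match/mismatch, gap open 50, no extension
    penalty)."""

    scoring: ScoringParams = field(default_factory=ScoringParams)
    uorf: UorfSearchParams = field(default_factory=UorfSearchParams)
    window: int = DEFAULT_WINDOW
    min_score: float = DEFAULT_MIN_SCORE
    reciprocal_heatmap: bool = True
    kaks_method: str = "YN00"
    gradient: str = DEFAULT_GRADIENT
    image_format: str = "png"
    output_dir: Path = Path("upep_out")
    seed: int = 0  # reserved for stochastic harnesses; the pipeline is deterministic

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = dict(raw)
        if "scoring" in kwargs:
            kwargs["scoring"] = ScoringParams(**kwargs["scoring"])
        if "uorf" in kwargs:
            kwargs["uorf"] = UorfSearchParams(**kwargs["uorf"])
        if "output_dir" in kwargs:
            kwargs["output_dir"] = Path(kwargs["output_dir"])
        return cls(**kwargs)


def _kaks_row(res: KaKsResult | None, err: str | None) -> dict[str, str]:
    if res is None:
        return {"ratio": "NA", "flags": err or "NA"}
    return {
        "ratio": "undefined" if res.ratio is None else f"{res.ratio:.4f}",
        "flags": ";".join(res.flags) or "-",
    }


def _write_kaks_tsv(report: PairedKaKsReport, path: Path) -> None:
    cols = ["region", "S", "N", "Sd", "Nd", "Ka", "Ks", "ratio", "kappa", "flags"]
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(cols)
        for name, res, err in (
            ("uORF", report.uorf, report.uorf_error),
            ("mORF", report.morf, report.morf_error),
        ):
            if res is None:
                w.writerow([name] + ["NA"] * 8 + [err or "NA"])
                continue
            w.writerow(
                [
                    name,
                    f"{res.S:.2f}",
                    f"{res.N:.2f}",
                    f"{res.Sd:.2f}",
                    f"{res.Nd:.2f}",
                    f"{res.Ka:.4f}",
                    f"{res.Ks:.4f}",
                    "undefined" if res.ratio is None else f"{res.ratio:.4f}",
                    "NA" if res.kappa is None else f"{res.kappa:.3f}",
                    ";".join(res.flags) or "-",
                ]
            )
        rr = report.ratio_of_ratios
        w.writerow(
            ["uORF/mORF", "", "", "", "", "", "",
             "undefined" if rr is None else f"{rr:.4f}", "", "-"]
        )


def _orf_features(t: Transcript) -> list[tuple[str, object]]:
    """ORF bars for the heatmap: mORF plus qualifying uORFs."""
    feats: list[tuple[str, object]] = []
    try:
        morf = find_morf(t)
    except NoMorfError:
        return feats
    feats.append(("mORF", morf))
    for k, u in enumerate(find_uorfs(t), start=1):
        feats.append((f"uORF{k}", u.interval))
    return feats


def _process_hit(
    query: Transcript, ref: Transcript, hit: SearchHit, cfg: RunConfig, hit_dir: Path
) -> dict[str, str]:
    hit_dir.mkdir(parents=True, exist_ok=True)
    aln = global_align(query.sequence, ref.sequence, cfg.scoring)
    (hit_dir / "aligned.txt").write_text(aln.interleaved())
    prof_q = compute_profile(aln, cfg.window, label=query.accession)
    profiles = [prof_q]
    features = [_orf_features(query)]
    if cfg.reciprocal_heatmap:
        profiles.append(reference_profile(aln, cfg.window, label=ref.accession))
        features.append(_orf_features(ref))
    heat = hit_dir / f"heatmap.{cfg.image_format}"
    render_heatmap(profiles, features, cfg.gradient, heat,
                   title=f"{query.accession} vs {ref.accession}")
    write_profile_tsv(prof_q, hit_dir / "profile.tsv")
    report = compare_uorf_morf(
        query, ref, (hit.query_uorf, hit.ref_uorf), cfg.kaks_method, alignment=aln
    )
    _write_kaks_tsv(report, hit_dir / "kaks.tsv")
    row = {
        "uorf_kaks": _kaks_row(report.uorf, report.uorf_error)["ratio"],
        "morf_kaks": _kaks_row(report.morf, report.morf_error)["ratio"],
        "alignment_score": f"{aln.score:.0f}",
    }
    return row


_SUMMARY_COLS = [
    "rank", "ref_accession", "query_uorf", "ref_uorf", "raw_score", "bits",
    "evalue", "alignment_score", "uorf_kaks", "morf_kaks", "status",
]


def run_conserved_upep_search(
    query: Transcript, db: UorfDatabase, cfg: RunConfig
) -> Path:
    """Run the full conserved-uPEP analysis; returns the summary TSV path.

    Per-hit artefacts (heatmap image, aligned text, profile and Ka/Ks
    TSVs) land in subdirectories named by reference accession and hit
    rank. A stage failure is recorded in the hit's ``status`` column
    and does not abort the remaining hits.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    hits = search_conserved(query, db, cfg.uorf, cfg.min_score)
    if not hits:
        logger.info("%s: no conserved uPEP candidates found", query.accession)
    rows: list[list[str]] = []
    for rank, hit in enumerate(hits, start=1):
        ref = db.transcripts.get(hit.ref_accession)
        qs, qe = hit.query_uorf.interval.as_one_based()
        rs, re_ = hit.ref_uorf.interval.as_one_based()
        row = {
            "rank": str(rank),
            "ref_accession": hit.ref_accession,
            "query_uorf": f"{qs}-{qe}",
            "ref_uorf": f"{rs}-{re_}",
            "raw_score": f"{hit.raw_score:.0f}",
            "bits": f"{hit.bit_like_score:.1f}",
            "evalue": f"{hit.significance:.3g}",
            "alignment_score": "NA",
            "uorf_kaks": "NA",
            "morf_kaks": "NA",
            "status": "ok",
        }
        if ref is None:
            row["status"] = "reference transcript missing from database bundle"
        else:
            hit_dir = out / f"hit{rank:03d}_{hit.ref_accession}"
            try:
                row.update(_process_hit(query, ref, hit, cfg, hit_dir))
            except UpepError as exc:
                row["status"] = f"failed: {exc}"
                logger.warning("hit %d (%s): %s", rank, hit.ref_accession, exc)
        rows.append([row[c] for c in _SUMMARY_COLS])
    summary = out / "summary.tsv"
    with open(summary, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(_SUMMARY_COLS)
        w.writerows(rows)
    return summary


def run_heatmap_only(q: Transcript, r: Transcript, cfg: RunConfig) -> Path:
    """Align a pair directly and render its heatmap; returns the image path.

    ORF bars come from the annotated CDS when present, otherwise from
    de novo mORF/uORF location. Also writes the aligned text and the
    query profile TSV next to the image.
    """
    out = Path(cfg.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    aln = global_align(q.sequence, r.sequence, cfg.scoring)
    (out / "aligned.txt").write_text(aln.interleaved())
    prof_q = compute_profile(aln, cfg.window, label=q.accession)
    profiles = [prof_q]
    features = [_orf_features(q)]
    if cfg.reciprocal_heatmap:
        profiles.append(reference_profile(aln, cfg.window, label=r.accession))
        features.append(_orf_features(r))
    heat = out / f"heatmap.{cfg.image_format}"
    render_heatmap(profiles, features, cfg.gradient, heat,
                   title=f"{q.accession} vs {r.accession}")
    write_profile_tsv(prof_q, out / "profile.tsv")
    return heat
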