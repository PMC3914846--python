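"""Deterministic synthetic transcript generator with planted structure.

Everything downstream — uORF finding, translated search, heatmaps,
Ka/Ks — is exercised on transcripts built here: RefSeq-like mRNAs with
a known CDS and uORFs planted at known coordinates, paired with a
diverged homologue whose conservation structure is controlled
parameter by parameter (UTR nucleotide identity, uORF amino-acid
identity, synonymous bias omega, indel rate).

The mutation model is intentionally simple: per-site substitution with
transition bias kappa = 2; coding regions are mutated per codon with
proposals accepted according to synonymy (synonymous changes always,
non-synonymous with probability omega, changes to stops never). This
creates the rank structure the analyses need without claiming
biological realism; see docs/methods.md for what it does not emulate.

Query transcripts are built so the planted uORFs are the only uORFs
present (no stray upstream AUGs), which makes the planted coordinates
an exact oracle for the uORF finder.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .errors import FixtureSpecError
from .kaks import SENSE_CODONS, STOP_CODONS, _AA, _CHANGES, _CODON_INDEX
from .model import OrfInterval, Transcript
from .uorfs import translate_codons

__all__ = [
    "FixtureSpec",
    "PairTruth",
    "make_transcript_pair",
    "make_database",
    "simulate_codon_pair",
]

_NTS = np.array(list("ACGT"))
#: transition partner of each nucleotide
_TS_PARTNER = {"A": "G", "G": "A", "C": "T", "T": "C"}
_KAPPA_BG = 2.0  # transition bias of the background mutation model

#: sense codons that are neither ATG nor able to seed a uORF start
_PLAIN_CODONS = tuple(c for c in SENSE_CODONS if c != "ATG")


@dataclass(frozen=True)
class FixtureSpec:
    """Geometry and divergence parameters of a synthetic transcript pair.

    Lengths are nucleotides except the codon counts; ``cds_len_codons``
    and ``uorf_len_codons`` count coding codons (start included, stop
    excluded). ``uorf_identity_aa`` is the target amino-acid identity
    of planted uORFs between the pair; ``background_identity_nt`` the
    target nucleotide identity of the UTRs. ``omega_uorf`` and
    ``omega_morf`` set the non-synonymous acceptance probability when
    mutating coding regions; ``indel_rate`` is the per-site indel
    probability outside coding regions.
    """

    seed: int = 0
    utr5_len: int = 300
    cds_len_codons: int = 300
    utr3_len: int = 200
    n_uorfs: int = 1
    uorf_len_codons: int = 25
    uorf_identity_aa: float = 1.0
    background_identity_nt: float = 0.7
    omega_uorf: float = 0.1
    omega_morf: float = 0.2
    indel_rate: float = 0.005

    def __post_init__(self) -> None:
        for name in ("uorf_identity_aa", "background_identity_nt", "indel_rate"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise FixtureSpecError(f"{name}={v} outside [0, 1]")
        for name in ("utr5_len", "cds_len_codons", "utr3_len", "uorf_len_codons"):
            if getattr(self, name) <= 0:
                raise FixtureSpecError(f"{name} must be positive")
        if self.n_uorfs < 0:
            raise FixtureSpecError("n_uorfs must be >= 0")
        if self.omega_uorf < 0 or self.omega_morf < 0:
            raise FixtureSpecError("omega must be >= 0")


@dataclass
class PairTruth:
    """Ground truth for one generated pair."""

    query_uorfs: list[OrfInterval]
    ref_uorfs: list[OrfInterval]
    query_cds: OrfInterval
    ref_cds: OrfInterval
    uorf_peptides_query: list[str]
    uorf_peptides_ref: list[str]
    spec: FixtureSpec

    def as_dict(self) -> dict:
        return {
            "query_uorfs": [[iv.start, iv.end] for iv in self.query_uorfs],
            "ref_uorfs": [[iv.start, iv.end] for iv in self.ref_uorfs],
            "query_cds": [self.query_cds.start, self.query_cds.end],
            "ref_cds": [self.ref_cds.start, self.ref_cds.end],
            "uorf_peptides_query": self.uorf_peptides_query,
            "uorf_peptides_ref": self.uorf_peptides_ref,
        }


# ---------------------------------------------------------------------------
# query-side construction
# ---------------------------------------------------------------------------

def _random_background(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(_NTS, size=length)) if length > 0 else ""


def _sample_codons(rng: np.random.Generator, n: int, prefix: str) -> str:
    """Sample n sense codons avoiding ATG trigrams in any frame.

    ``prefix`` supplies the two preceding characters so cross-codon
    windows are checked too.
    """
    out: list[str] = []
    tail = prefix[-2:]
    for _ in range(n):
        for _attempt in range(200):
            c = _PLAIN_CODONS[rng.integers(len(_PLAIN_CODONS))]
            if "ATG" in (tail + c):
                continue
            out.append(c)
            tail = c[-2:]
            break
        else:  # pragma: no cover - alphabet makes this unreachable
            raise FixtureSpecError("codon sampling failed")
    return "".join(out)


def _pick_stop(rng: np.random.Generator, prefix: str) -> str:
    stops = sorted(STOP_CODONS)
    for _attempt in range(50):
        s = stops[rng.integers(len(stops))]
        if "ATG" not in (prefix[-2:] + s):
            return s
    return "TAA"


def _uorf_block(rng: np.random.Generator, n_codons: int) -> str:
    """ATG + (n_codons - 1) sense codons + stop, free of internal ATGs."""
    body = _sample_codons(rng, n_codons - 1, prefix="ATG")
    return "ATG" + body + _pick_stop(rng, "ATG" + body)


def _scrub_stray_atgs(
    chars: list[str], protect: list[OrfInterval], upto: int, rng: np.random.Generator
) -> None:
    """Mutate background nucleotides until no un-planted ATG starts
    before ``upto``. Planted intervals are never touched; replacing an
    offending character with C can never create a new ATG."""
    starts = {iv.start for iv in protect}

    def inside(i: int) -> bool:
        return any(iv.start <= i < iv.end for iv in protect)

    for _round in range(10):
        dirty = False
        for p in range(0, upto - 2):
            if chars[p] == "A" and chars[p + 1] == "T" and chars[p + 2] == "G" and p not in starts:
                free = [i for i in (p, p + 1, p + 2) if not inside(i)]
                chars[free[int(rng.integers(len(free)))]] = "C"
                dirty = True
        if not dirty:
            return
    raise FixtureSpecError("could not scrub stray upstream ATGs")  # pragma: no cover


def _layout_utr5(spec: FixtureSpec, rng: np.random.Generator) -> tuple[str, list[OrfInterval], list[str]]:
    """Assemble the 5'UTR with planted uORF blocks and return it with
    the planted intervals and peptides."""
    span = 3 * (spec.uorf_len_codons + 1)
    total = spec.n_uorfs * span
    min_gap = 3
    free = spec.utr5_len - total - min_gap * (spec.n_uorfs + 1)
    if spec.n_uorfs > 0 and free < 0:
        raise FixtureSpecError(
            f"{spec.n_uorfs} uORFs of {span} nt do not fit a {spec.utr5_len} nt 5'UTR"
        )
    if spec.n_uorfs == 0:
        utr = _random_background(rng, spec.utr5_len)
        return utr, [], []
    extra = rng.multinomial(free, np.full(spec.n_uorfs + 1, 1.0 / (spec.n_uorfs + 1)))
    gaps = [min_gap + int(e) for e in extra]
    pieces: list[str] = []
    intervals: list[OrfInterval] = []
    peptides: list[str] = []
    pos = 0
    for k in range(spec.n_uorfs):
        g = _random_background(rng, gaps[k])
        pieces.append(g)
        pos += gaps[k]
        block = _uorf_block(rng, spec.uorf_len_codons)
        pieces.append(block)
        intervals.append(OrfInterval(pos, pos + span))
        peptides.append(translate_codons(block[:-3]))
        pos += span
    pieces.append(_random_background(rng, gaps[-1]))
    return "".join(pieces), intervals, peptides


def _make_query(spec: FixtureSpec, rng: np.random.Generator, accession: str) -> tuple[Transcript, list[OrfInterval], list[str]]:
    utr5, uorf_ivs, peptides = _layout_utr5(spec, rng)
    cds = "ATG" + _sample_codons(rng, spec.cds_len_codons - 1, prefix="ATG")
    cds += _pick_stop(rng, cds)
    utr3 = _random_background(rng, spec.utr3_len)
    chars = list(utr5 + cds + utr3)
    _scrub_stray_atgs(chars, uorf_ivs, upto=spec.utr5_len, rng=rng)
    seq = "".join(chars)
    cds_iv = OrfInterval(spec.utr5_len, spec.utr5_len + len(cds))
    t = Transcript(accession, seq, cds=cds_iv, species="query_species")
    return t, uorf_ivs, peptides


# ---------------------------------------------------------------------------
# reference derivation (mutation model)
# ---------------------------------------------------------------------------

def _mutate_nt(nt: str, rng: np.random.Generator) -> str:
    """kappa-biased single-nucleotide substitution (always changes)."""
    if rng.random() < _KAPPA_BG / (_KAPPA_BG + 2.0):
        return _TS_PARTNER[nt]
    others = [x for x in "ACGT" if x != nt and x != _TS_PARTNER[nt]]
    return others[int(rng.integers(2))]


def _mutate_background(seg: str, spec: FixtureSpec, rng: np.random.Generator, *, indels: bool) -> str:
    p_sub = 1.0 - spec.background_identity_nt
    out: list[str] = []
    for ch in seg:
        if indels and rng.random() < spec.indel_rate:
            if rng.random() < 0.5:  # insertion before this site
                out.append(_random_background(rng, int(rng.integers(1, 4))))
            else:  # deletion of this site
                continue
        out.append(_mutate_nt(ch, rng) if rng.random() < p_sub else ch)
    return "".join(out)


def _substitute_nonsyn(codon: str, rng: np.random.Generator) -> str:
    """One accepted non-synonymous single-nucleotide change (never a stop)."""
    for _ in range(100):
        pos = int(rng.integers(3))
        cand = codon[:pos] + _mutate_nt(codon[pos], rng) + codon[pos + 1 :]
        if cand not in STOP_CODONS and _AA[cand] != _AA[codon]:
            return cand
    return codon  # pragma: no cover - every sense codon has a nonsyn neighbour


def _mutate_uorf_codons(seg: str, identity_aa: float, omega: float, rng: np.random.Generator) -> str:
    """Mutate a planted uORF to exactly the target amino-acid identity.

    round((1 - identity_aa) * L) interior codons (the peptide length L
    includes the fixed start Met) receive one non-synonymous change
    each; synonymous substitutions are layered on every interior codon
    at the Poisson rate implied by the acceptance model (accepted
    syn : nonsyn events = 0.24 : 0.76 omega, with -ln(identity) nonsyn
    events per codon). Planting the divergence by count rather than in
    expectation keeps short peptides from drifting far from the target
    through sampling noise. With omega = 0 no amino acid ever changes
    and a fixed synonymous rate supplies nucleotide divergence.
    """
    codons = [seg[i : i + 3] for i in range(0, len(seg), 3)]
    interior = list(range(1, len(codons) - 1))  # skip start Met and stop
    L = len(codons) - 1  # peptide length incl. Met
    if identity_aa >= 1.0:
        return seg
    if omega <= 0.0:
        # unit proposal rate under the acceptance model: ~24% of random
        # single-nt proposals are synonymous
        n_change, lam_syn = 0, 0.24
    else:
        n_change = min(round((1.0 - identity_aa) * L), len(interior))
        lam_syn = -math.log(identity_aa) * 0.24 / (0.76 * min(omega, 1.0))
    for k in rng.choice(interior, size=n_change, replace=False) if n_change else []:
        codons[k] = _substitute_nonsyn(codons[k], rng)
    for k in interior:
        for _event in range(rng.poisson(lam_syn)):
            cur = codons[k]
            for _try in range(60):  # Met/Trp have no synonymous neighbour
                pos = int(rng.integers(3))
                cand = cur[:pos] + _mutate_nt(cur[pos], rng) + cur[pos + 1 :]
                if cand not in STOP_CODONS and _AA[cand] == _AA[cur]:
                    codons[k] = cand
                    break
    return "".join(codons)


def _mutate_codons(seg: str, rate: float, omega: float, rng: np.random.Generator, *, fix_ends: bool) -> str:
    """Per-codon proposal/acceptance mutation of an in-frame region.

    ``fix_ends`` keeps the first (start) and last (stop) codon intact
    so the homologue remains a findable ORF.
    """
    codons = [seg[i : i + 3] for i in range(0, len(seg), 3)]
    first, last = (1, len(codons) - 1) if fix_ends else (0, len(codons))
    for k in range(first, last):
        cur = codons[k]
        n_prop = rng.poisson(rate)
        for _ in range(n_prop):
            pos = int(rng.integers(3))
            nt = _mutate_nt(cur[pos], rng)
            cand = cur[:pos] + nt + cur[pos + 1 :]
            if cand in STOP_CODONS:
                continue
            if _AA[cand] != _AA[cur] and rng.random() >= min(omega, 1.0):
                continue
            cur = cand
        codons[k] = cur
    return "".join(codons)


def make_transcript_pair(spec: FixtureSpec) -> tuple[Transcript, Transcript, PairTruth]:
    """Build a query transcript and its diverged reference homologue.

    Fully reproducible from ``spec.seed``. The truth record carries the
    planted uORF/CDS coordinates on both transcripts and the planted
    peptides.
    """
    rng = np.random.default_rng(spec.seed)
    query, uorf_ivs, peptides = _make_query(spec, rng, accession=f"SYN{spec.seed:06d}.1")

    # Segment the query so indels never touch coding regions and
    # reference coordinates can be tracked exactly.
    bounds: list[tuple[int, int, str]] = []  # (start, end, kind)
    cursor = 0
    for iv in uorf_ivs:
        bounds.append((cursor, iv.start, "bg"))
        bounds.append((iv.start, iv.end, "uorf"))
        cursor = iv.end
    cds_iv = query.cds
    assert cds_iv is not None
    bounds.append((cursor, cds_iv.start, "bg"))
    bounds.append((cds_iv.start, cds_iv.end, "cds"))
    bounds.append((cds_iv.end, len(query.sequence), "bg"))

    cds_rate = 3.0 * (1.0 - spec.background_identity_nt)

    ref_parts: list[str] = []
    ref_uorfs: list[OrfInterval] = []
    ref_cds: OrfInterval | None = None
    pos = 0
    for start, end, kind in bounds:
        seg = query.sequence[start:end]
        if kind == "bg":
            new = _mutate_background(seg, spec, rng, indels=True)
        elif kind == "uorf":
            new = _mutate_uorf_codons(seg, spec.uorf_identity_aa, spec.omega_uorf, rng)
            ref_uorfs.append(OrfInterval(pos, pos + len(new)))
        else:
            new = _mutate_codons(seg, cds_rate, spec.omega_morf, rng, fix_ends=True)
            ref_cds = OrfInterval(pos, pos + len(new))
        ref_parts.append(new)
        pos += len(new)
    assert ref_cds is not None
    ref = Transcript(
        accession=f"SYN{spec.seed:06d}r.1",
        sequence="".join(ref_parts),
        cds=ref_cds,
        species="reference_species",
    )
    truth = PairTruth(
        query_uorfs=uorf_ivs,
        ref_uorfs=ref_uorfs,
        query_cds=cds_iv,
        ref_cds=ref_cds,
        uorf_peptides_query=peptides,
        uorf_peptides_ref=[
            translate_codons(ref.sequence[iv.start : iv.end - 3]) for iv in ref_uorfs
        ],
        spec=spec,
    )
    return query, ref, truth


def make_database(
    n: int,
    spec: FixtureSpec,
    planted: list[Transcript] | None = None,
    n_flagged: int = 0,
) -> list[Transcript]:
    """Generate ``n`` decoy transcripts plus planted homologue carriers.

    Decoys are independent query-style transcripts (each with its own
    random uORFs) derived from ``spec`` with per-decoy seeds. The first
    ``n_flagged`` decoys are emitted with an undefined mORF start (CDS
    annotation stripped, flag set) to exercise the database exclusion
    rule. ``planted`` transcripts are appended unchanged.
    """
    if n < 1:
        raise FixtureSpecError("n must be >= 1")
    if n_flagged > n:
        raise FixtureSpecError("n_flagged cannot exceed n")
    out: list[Transcript] = []
    base = np.random.default_rng(spec.seed).integers(0, 2**31 - 1)
    for k in range(n):
        sub = replace(spec, seed=int((base + 7919 * (k + 1)) % 2**31))
        rng = np.random.default_rng(sub.seed)
        t, _, _ = _make_query(sub, rng, accession=f"DEC{k:05d}.1")
        if k < n_flagged:
            t = Transcript(
                t.accession, t.sequence, cds=None, species=t.species,
                morf_start_undefined=True,
            )
        out.append(t)
    out.extend(planted or [])
    return out


# ---------------------------------------------------------------------------
# codon-model sequence pair simulator (oracle for the rate estimators)
# ---------------------------------------------------------------------------

def simulate_codon_pair(
    n_codons: int,
    t: float,
    omega: float,
    kappa: float = 2.0,
    rng: np.random.Generator | int | None = None,
) -> tuple[str, str]:
    """Simulate a codon-aligned sequence pair at divergence ``t``.

    A continuous-time codon model: single-nucleotide exchanges only,
    rate multiplied by ``kappa`` for transitions and by ``omega`` for
    non-synonymous changes; changes to stop codons are forbidden. Rates
    are scaled so ``t`` is the expected number of nucleotide
    substitutions per codon between the two sequences. The ancestor is
    drawn uniformly over the 61 sense codons and one lineage is evolved
    for time ``t`` (an exchangeable stand-in for two branches of t/2).
    """
    if isinstance(rng, (int, np.integer)) or rng is None:
        rng = np.random.default_rng(rng)
    n61 = len(SENSE_CODONS)
    rates = np.zeros((n61, n61))
    for i, codon in enumerate(SENSE_CODONS):
        for ch in _CHANGES[codon]:
            if ch.to_stop:
                continue
            target = codon[: ch.pos] + ch.target_nt + codon[ch.pos + 1 :]
            r = (kappa if ch.is_ts else 1.0) * (1.0 if ch.is_syn else omega)
            rates[i, _CODON_INDEX[target]] = r
    exit_rates = rates.sum(axis=1)
    scale = exit_rates.mean()
    if scale <= 0:
        raise FixtureSpecError("degenerate codon model (all rates zero)")
    rates /= scale
    exit_rates /= scale

    anc_idx = rng.integers(n61, size=n_codons)
    der_idx = anc_idx.copy()
    for k in range(n_codons):
        i = int(der_idx[k])
        clock = 0.0
        while exit_rates[i] > 0:
            clock += rng.exponential(1.0 / exit_rates[i])
            if clock > t:
                break
            i = int(rng.choice(n61, p=rates[i] / exit_rates[i]))
        der_idx[k] = i
    seq1 = "".join(SENSE_CODONS[i] for i in anc_idx)
    seq2 = "".join(SENSE_CODONS[i] for i in der_idx)
    return seq1, seq2
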