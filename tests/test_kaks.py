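"""Ka/Ks estimation: codon alignment extraction, NG86/YN00 correctness."""

import itertools
import math

import numpy as np
import pytest

from oracles import pathway_differences
from upep import (
    InsufficientDataError,
    OrfInterval,
    ScoringParams,
    codon_align,
    compare_uorf_morf,
    estimate_kaks,
    find_uorfs,
    global_align,
    make_transcript_pair,
    simulate_codon_pair,
)
from upep.fixtures import FixtureSpec
from upep.kaks import SENSE_CODONS, CodonAlignment, _NG86_S, _pathway_counts


def _pairs(s1: str, s2: str):
    return [(s1[i : i + 3], s2[i : i + 3]) for i in range(0, len(s1), 3)]


class TestCodonAlign:
    def test_identical_orfs_gap_free(self):
        orf = "ATG" + "GCT" * 10 + "TAA"
        seq = "CCCCC" + orf + "GGGGG"
        aln = global_align(seq, seq)
        c = codon_align(aln, OrfInterval(5, 5 + len(orf)), OrfInterval(5, 5 + len(orf)))
        # stop codon excluded silently: 11 coding codons, none dropped
        assert c.n_codons == len(orf) // 3 - 1
        assert c.dropped_codons == 0

    def test_internal_gap_drops_overlapping_codons(self):
        orf = "ATG" + "GCTGAAGTTCAAAGA" * 3 + "TAA"
        q = "CCCCC" + orf + "GGGGG"
        # delete one codon from the reference copy of the ORF
        r = "CCCCC" + orf[:9] + orf[12:] + "GGGGG"
        aln = global_align(q, r, ScoringParams(gap_open=10))
        c = codon_align(aln, OrfInterval(5, 5 + len(orf)), OrfInterval(5, 5 + len(orf) - 3))
        assert c.dropped_codons >= 1
        assert c.n_codons >= len(orf) // 3 - 1 - 2

    def test_ambiguous_codon_dropped(self):
        orf = "ATG" + "GCT" * 9 + "TAA"
        seq = "CC" + orf + "GG"
        mutated = seq.replace("GCTGCT", "GCTGNT", 1)
        aln = global_align(seq, mutated)
        c = codon_align(aln, OrfInterval(2, 2 + len(orf)), OrfInterval(2, 2 + len(orf)))
        assert c.dropped_codons == 1
        assert c.n_codons == 10 - 1  # ATG + 9 coding codons, one dropped

    def test_no_clean_codons_raises(self):
        aln = global_align("NNNNNNTAA", "NNNNNNTAA")
        with pytest.raises(InsufficientDataError):
            codon_align(aln, OrfInterval(0, 9), OrfInterval(0, 9))


class TestSiteCounts:
    def test_phe_codon_standard_code_degeneracy(self):
        """TTT has exactly one synonymous change in three at position 3."""
        assert _NG86_S["TTT"] == pytest.approx(1 / 3)
        c = CodonAlignment(_pairs("TTT" * 30, "TTT" * 30), 0)
        r = estimate_kaks(c, "NG86")
        assert r.S == pytest.approx(30 / 3)
        assert r.S + r.N == pytest.approx(3 * 30)

    def test_sites_sum_to_three_per_codon_both_methods(self, rng):
        s1, s2 = simulate_codon_pair(200, 0.4, 0.5, rng=rng)
        c = CodonAlignment(_pairs(s1, s2), 0)
        for m in ("NG86", "YN00"):
            r = estimate_kaks(c, m)
            assert r.S + r.N == pytest.approx(3 * 200, rel=1e-9)


class TestExamples:
    def test_identical_sequences_undefined_ratio(self):
        c = CodonAlignment(_pairs("GCTAAA" * 50, "GCTAAA" * 50), 0)
        for m in ("NG86", "YN00"):
            r = estimate_kaks(c, m)
            assert r.Ka == 0 and r.Ks == 0
            assert r.ratio is None and "undefined_ratio" in r.flags

    def test_single_synonymous_third_position_change(self):
        q = "GCT" * 100
        r = "GCC" + "GCT" * 99
        res = estimate_kaks(CodonAlignment(_pairs(q, r), 0), "NG86")
        assert res.Nd == 0 and res.Sd == 1
        assert res.Ka == 0 and res.Ks > 0
        res = estimate_kaks(CodonAlignment(_pairs(q, r), 0), "YN00")
        assert res.Nd == 0 and res.Ka == 0 and res.Ks > 0

    def test_saturation_flagged_not_raised(self, rng):
        s1, s2 = simulate_codon_pair(80, 60.0, 1.0, rng=rng)
        r = estimate_kaks(CodonAlignment(_pairs(s1, s2), 0), "NG86")
        assert r.ratio is None
        assert any(f.startswith("saturated") for f in r.flags)


class TestPathwayOracle:
    def test_all_sense_codon_pairs_match_enumeration(self):
        """Pathway-averaged (Sd, Nd) equal an independent permutation
        enumeration for every one of the 61 x 61 codon pairs."""
        for c1, c2 in itertools.product(SENSE_CODONS, repeat=2):
            sd, nd, *_ = _pathway_counts(c1, c2)
            esd, end_ = pathway_differences(c1, c2)
            assert not math.isnan(esd), (c1, c2)
            assert sd == pytest.approx(esd), (c1, c2)
            assert nd == pytest.approx(end_), (c1, c2)
            ndiff = sum(a != b for a, b in zip(c1, c2))
            assert sd + nd == pytest.approx(ndiff)

    def test_ts_tv_split_is_consistent(self):
        for c1, c2 in itertools.product(SENSE_CODONS, repeat=2):
            sd, nd, sdts, sdtv, ndts, ndtv = _pathway_counts(c1, c2)
            assert sdts + sdtv == pytest.approx(sd)
            assert ndts + ndtv == pytest.approx(nd)


class TestSymmetry:
    def test_ng86_exactly_symmetric(self, rng):
        s1, s2 = simulate_codon_pair(150, 0.5, 0.3, rng=rng)
        fwd = estimate_kaks(CodonAlignment(_pairs(s1, s2), 0), "NG86")
        rev = estimate_kaks(CodonAlignment(_pairs(s2, s1), 0), "NG86")
        assert (fwd.S, fwd.N, fwd.Sd, fwd.Nd, fwd.Ka, fwd.Ks) == (
            rev.S, rev.N, rev.Sd, rev.Nd, rev.Ka, rev.Ks,
        )

    def test_yn00_symmetric_within_tolerance(self, rng):
        s1, s2 = simulate_codon_pair(150, 0.5, 0.3, rng=rng)
        fwd = estimate_kaks(CodonAlignment(_pairs(s1, s2), 0), "YN00")
        rev = estimate_kaks(CodonAlignment(_pairs(s2, s1), 0), "YN00")
        assert fwd.Ka == pytest.approx(rev.Ka, rel=1e-9)
        assert fwd.Ks == pytest.approx(rev.Ks, rel=1e-9)


class TestParameterRecovery:
    def test_omega_recovery_small_grid(self):
        """Reduced-scale sanity check of estimator calibration (the full
        grid runs in the acceptance suite)."""
        for omega in (0.1, 1.0):
            yn = []
            for rep in range(15):
                s1, s2 = simulate_codon_pair(400, 0.3, omega, rng=3_000 + rep)
                r = estimate_kaks(CodonAlignment(_pairs(s1, s2), 0), "YN00")
                yn.append(r.ratio)
            assert np.mean(yn) == pytest.approx(omega, rel=0.25)


class TestCompareUorfMorf:
    def test_synonymous_only_uorf_beats_neutral_morf(self):
        spec = FixtureSpec(
            seed=5, uorf_identity_aa=0.9, omega_uorf=0.0, omega_morf=1.0,
            background_identity_nt=0.8, indel_rate=0.0,
        )
        q, r, _ = make_transcript_pair(spec)
        qu, ru = find_uorfs(q)[0], find_uorfs(r)[0]
        rep = compare_uorf_morf(q, r, (qu, ru), "YN00")
        assert rep.uorf.Ka == 0.0
        assert rep.uorf.ratio == 0.0
        assert rep.morf.ratio > rep.uorf.ratio
        assert rep.ratio_of_ratios == 0.0

    def test_identical_transcripts_report_undefined(self):
        q, _, _ = make_transcript_pair(FixtureSpec(seed=6))
        qu = find_uorfs(q)[0]
        rep = compare_uorf_morf(q, q, (qu, qu), "NG86")
        assert rep.uorf.ratio is None and rep.morf.ratio is None
        assert rep.ratio_of_ratios is None

    def test_partial_report_when_uorf_unusable(self):
        q, r, _ = make_transcript_pair(FixtureSpec(seed=7, indel_rate=0.0))
        # poison the uORF interval with an out-of-range span
        from upep.model import UorfRecord

        bad = OrfInterval(len(q.sequence) - 3, len(q.sequence) + 300)
        bad_rec = UorfRecord("x", bad, "M")
        rep = compare_uorf_morf(q, r, (bad_rec, bad_rec), "NG86")
        assert rep.uorf is None and rep.uorf_error
        assert rep.morf is not None
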