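"""Windowed identity profile: formula, oracle equivalence, rendering."""

import numpy as np
import pytest

from oracles import clipped_window_profile
from upep import (
    AlignmentResult,
    ParameterError,
    ScoringParams,
    compute_profile,
    global_align,
    reference_profile,
)
from upep.profile import profile_to_rgb, render_heatmap, write_profile_tsv


def _fake_alignment(q_aligned: str, match_seq) -> AlignmentResult:
    """AlignmentResult stub driven by an explicit match sequence."""
    r_dummy = "".join("A" if c != "-" else "C" for c in q_aligned)
    return AlignmentResult(
        q_aligned=q_aligned,
        r_aligned=r_dummy,
        match_seq=np.asarray(match_seq, dtype=np.uint8),
        score=0.0,
        params=ScoringParams(),
    )


class TestFormula:
    def test_hand_evaluated_branches(self):
        """M=[1,0,1,1,0], w=3: the three printed branches give
        [0.5, 2/3, 2/3, 2/3, 0.5]."""
        a = _fake_alignment("ACGTA", [1, 0, 1, 1, 0])
        p = compute_profile(a, 3)
        np.testing.assert_allclose(
            p.values, [0.5, 2 / 3, 2 / 3, 2 / 3, 0.5]
        )

    def test_identical_sequences_give_all_ones(self):
        seq = "ACGTACGTACGTACGTACGT"
        aln = global_align(seq, seq)
        for w in (1, 3, 5, 21):
            p = compute_profile(aln, w)
            assert p.q == len(seq)
            np.testing.assert_array_equal(p.values, np.ones(len(seq)))

    @pytest.mark.parametrize("w", [0, 2, 4, -3])
    def test_even_or_nonpositive_window_rejected(self, w):
        a = _fake_alignment("ACGT", [1, 1, 1, 1])
        with pytest.raises(ParameterError):
            compute_profile(a, w)

    def test_window_larger_than_2m_minus_1_rejected(self):
        a = _fake_alignment("ACG", [1, 1, 1])
        with pytest.raises(ParameterError):
            compute_profile(a, 7)


def _random_fake_alignment(rng):
    m = int(rng.integers(5, 120))
    chars = []
    for _ in range(m):
        chars.append("-" if rng.random() < 0.15 else "ACGT"[rng.integers(4)])
    if all(c == "-" for c in chars):
        chars[0] = "A"
    M = (rng.random(m) < 0.6).astype(np.uint8)
    return _fake_alignment("".join(chars), M)


class TestOracleEquivalence:
    def test_matches_clipped_window_oracle(self, rng):
        """The three-branch formula equals direct clipped-window
        averaging (which also verifies the branch normalisers equal the
        clipped-window counts)."""
        for _ in range(400):
            a = _random_fake_alignment(rng)
            w = int(rng.choice([3, 5, 21]))
            if w > 2 * a.m - 1:
                w = 3
            got = compute_profile(a, w).values
            expected = clipped_window_profile(a.q_aligned, a.match_seq, w)
            np.testing.assert_allclose(got, expected, rtol=0, atol=0)

    def test_profile_length_is_ungapped_query_length(self, rng):
        for _ in range(100):
            a = _random_fake_alignment(rng)
            p = compute_profile(a, 5)
            assert p.q == len(a.q_aligned.replace("-", ""))
            assert np.all((p.values >= 0) & (p.values <= 1))

    def test_reciprocity_at_full_identity(self):
        seq = "ATGCCGTTAGACCA" * 3
        aln = global_align(seq, seq)
        np.testing.assert_array_equal(
            compute_profile(aln, 5).values, reference_profile(aln, 5).values
        )

    def test_gap_columns_depress_identity(self):
        # an insertion in the reference lowers the profile near the gap
        q, r = "ACGTACGTACGT", "ACGTACTTTTTTGTACGT"
        aln = global_align(q, r, ScoringParams(gap_open=5))
        p = compute_profile(aln, 5)
        assert p.values.min() < 1.0


class TestRendering:
    def test_uniform_profile_maps_to_top_colour(self):
        vals = np.ones(50)
        rgb = profile_to_rgb(vals, "viridis")
        assert rgb.shape == (50, 3)
        assert np.allclose(rgb, rgb[0])  # uniform strip
        import matplotlib

        top = matplotlib.colormaps["viridis"](1.0)[:3]
        assert np.allclose(rgb[0], top)

    def test_conserved_block_visible_at_planted_coordinates(self, default_pair):
        """The planted uORF produces a high-identity block exactly at its
        query coordinates, asserted on rendered cell colours."""
        query, ref, truth = default_pair
        aln = global_align(query.sequence, ref.sequence)
        p = compute_profile(aln, 21)
        rgb = profile_to_rgb(p.values)
        iv = truth.query_uorfs[0]
        inside = p.values[iv.start + 10 : iv.end - 10]
        # default pair: uORF fully conserved, background diverged
        assert inside.mean() > 0.95
        utr_outside = np.concatenate([p.values[: max(iv.start - 21, 1)]])
        assert utr_outside.mean() < 0.9
        import matplotlib

        top = matplotlib.colormaps["viridis"](1.0)[:3]
        frac_top = np.mean(
            [np.allclose(c, top) for c in rgb[iv.start + 10 : iv.end - 10]]
        )
        assert frac_top > 0.8

    def test_one_and_two_strip_rendering(self, tmp_path, default_pair):
        query, ref, truth = default_pair
        aln = global_align(query.sequence, ref.sequence)
        pq = compute_profile(aln, 21, label="Q")
        pr = reference_profile(aln, 21, label="R")
        single = render_heatmap(
            [pq], [[("mORF", truth.query_cds)]], out=tmp_path / "one.png"
        )
        double = render_heatmap(
            [pq, pr],
            [
                [("mORF", truth.query_cds), ("uORF1", truth.query_uorfs[0])],
                [("mORF", truth.ref_cds)],
            ],
            out=tmp_path / "two.svg",
        )
        assert single.exists() and single.stat().st_size > 0
        assert double.exists() and b"<svg" in double.read_bytes()[:300]

    def test_profile_tsv_row_count(self, tmp_path):
        a = _fake_alignment("AC-GT", [1, 1, 0, 1, 0])
        p = compute_profile(a, 3)
        out = tmp_path / "p.tsv"
        write_profile_tsv(p, out)
        lines = out.read_text().strip().splitlines()
        assert len(lines) - 1 == p.q == 4
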