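"""mORF location and uORF enumeration against a brute-force oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oracles import enumerate_uorfs
from upep import (
    NoMorfError,
    OrfInterval,
    Transcript,
    UorfSearchParams,
    find_morf,
    find_uorfs,
)


class TestFindMorf:
    def test_annotation_takes_precedence(self):
        # annotated CDS wins even though a longer de novo ORF exists
        seq = "ATGAAAAAAAAAAAATAA" + "ATGGCTTAA"
        t = Transcript("t", seq, cds=OrfInterval(18, 27))
        assert find_morf(t) == OrfInterval(18, 27)

    def test_longest_forward_orf(self):
        t = Transcript("t", "AAATGGCTTAAGG")
        assert find_morf(t) == OrfInterval(2, 11)

    def test_tie_broken_five_prime(self):
        # two 6-nt ORFs in different frames; the 5'-most start wins
        seq = "ATGTAACATGTAG"
        assert find_morf(Transcript("t", seq)).start == 0

    def test_no_start_codon(self):
        with pytest.raises(NoMorfError):
            find_morf(Transcript("t", "CCCCCC"))

    def test_start_without_stop(self):
        with pytest.raises(NoMorfError):
            find_morf(Transcript("t", "ATGAAAAAA"))


def _planted_transcript():
    """5-codon and 12-codon uORFs ahead of an annotated CDS."""
    u1 = "ATG" + "GCT" * 4 + "TAA"  # 5 coding codons incl. Met
    u2 = "ATG" + "GAA" * 11 + "TGA"  # 12 coding codons incl. Met
    utr = "CCC" + u1 + "CC" + u2 + "CCCC"
    cds = "ATG" + "CAT" * 30 + "TAG"
    seq = utr + cds + "CCCCC"
    t = Transcript("planted", seq, cds=OrfInterval(len(utr), len(utr) + len(cds)))
    return t, u1, u2, utr


class TestFindUorfs:
    def test_length_filter(self):
        t, u1, u2, utr = _planted_transcript()
        found = find_uorfs(t, UorfSearchParams(min_len_codons=10))
        assert [u.length_codons for u in found] == [12]
        both = find_uorfs(t, UorfSearchParams(min_len_codons=1))
        assert [u.length_codons for u in both] == [5, 12]

    def test_peptides_and_coordinates(self):
        t, u1, u2, utr = _planted_transcript()
        found = find_uorfs(t, UorfSearchParams(min_len_codons=1))
        assert found[0].peptide == "MAAAA"
        assert found[1].peptide == "M" + "E" * 11
        assert found[0].interval.start == 3
        assert all(u.overlap_nt == 0 for u in found)

    def test_overlap_filter(self):
        # uAUG at 4, mORF at 40; the uORF's first in-frame stop is TGA at
        # 67..70, i.e. its end lies 30 nt into the CDS.
        seq = list("G" * 73)
        seq[0:4] = "CCCC"
        seq[4:7] = "ATG"
        seq[40:43] = "ATG"
        seq[67:70] = "TGA"
        t = Transcript("ov", "".join(seq), cds=OrfInterval(40, 73))
        dropped = find_uorfs(t, UorfSearchParams(min_len_codons=1, max_overlap_nt=0))
        assert [u.interval.start for u in dropped] == []
        kept = find_uorfs(t, UorfSearchParams(min_len_codons=1, max_overlap_nt=50))
        assert [(u.interval.start, u.interval.end, u.overlap_nt) for u in kept] == [
            (4, 70, 30)
        ]

    def test_search_limit_restricts_starts(self):
        t, *_ = _planted_transcript()
        p = UorfSearchParams(min_len_codons=1, search_limit_nt=10)
        found = find_uorfs(t, p)
        assert all(u.interval.start < 10 for u in found)


def _random_transcript(rng) -> Transcript:
    n = int(rng.integers(120, 600))
    seq = "".join(np.array(list("ACGT"))[rng.integers(4, size=n)])
    return Transcript(f"r{n}", seq)


PARAM_GRID = [
    UorfSearchParams(1, 0, None),
    UorfSearchParams(3, 0, None),
    UorfSearchParams(10, 0, None),
    UorfSearchParams(1, 30, None),
    UorfSearchParams(3, 60, 200),
]


class TestOracleEquivalence:
    def test_matches_brute_force_enumeration(self, rng):
        checked = 0
        for _ in range(300):
            t = _random_transcript(rng)
            try:
                morf = find_morf(t)
            except NoMorfError:
                continue
            for p in PARAM_GRID:
                expected = enumerate_uorfs(
                    t.sequence, morf.start, p.min_len_codons, p.max_overlap_nt, p.search_limit_nt
                )
                got = find_uorfs(t, p)
                assert [
                    (u.interval.start, u.interval.end, u.overlap_nt, u.peptide) for u in got
                ] == [tuple(e) for e in expected]
                checked += 1
        assert checked >= 300  # enough random instances actually compared

    def test_filter_monotonicity(self, rng):
        for _ in range(60):
            t = _random_transcript(rng)
            try:
                find_morf(t)
            except NoMorfError:
                continue
            loose = {
                (u.interval.start, u.interval.end)
                for u in find_uorfs(t, UorfSearchParams(1, 60, None))
            }
            tight = {
                (u.interval.start, u.interval.end)
                for u in find_uorfs(t, UorfSearchParams(5, 0, None))
            }
            assert tight <= loose


@settings(max_examples=60, deadline=None, derandomize=True)
@given(st.text(alphabet="ACGT", min_size=30, max_size=200), st.integers(1, 6))
def test_returned_uorfs_satisfy_contract(seq, min_len):
    """Every reported uORF starts with ATG, ends with a stop, lies 5' of
    the mORF, and respects the length filter."""
    t = Transcript("h", seq)
    try:
        morf = find_morf(t)
    except NoMorfError:
        return
    for u in find_uorfs(t, UorfSearchParams(min_len_codons=min_len, max_overlap_nt=9)):
        s, e = u.interval.start, u.interval.end
        assert seq[s : s + 3] == "ATG"
        assert seq[e - 3 : e] in {"TAA", "TAG", "TGA"}
        assert s < morf.start
        assert u.length_codons >= min_len
        assert u.overlap_nt == max(0, e - morf.start)
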