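"""Affine-gap promoter alignment and conserved-region extraction."""

import functools
import itertools

import numpy as np
import pytest

import conscan as cs

MATCH, MISMATCH, OPEN, EXT = 1.0, -1.0, -5.0, -1.0


def exhaustive_best_score(a: str, b: str) -> float:
    """Optimal global affine-gap score by recursion over all alignments.

    Plain three-state recursion with memoization; a length-k gap costs
    OPEN + (k-1) * EXT.  Independent of the DP implementation under test.
    """

    @functools.lru_cache(maxsize=None)
    def best(i: int, j: int, state: int) -> float:
        # state: 0 none/diagonal, 1 gap-in-b open, 2 gap-in-a open
        if i == len(a) and j == len(b):
            return 0.0
        options = []
        if i < len(a) and j < len(b):
            s = MATCH if a[i] == b[j] else MISMATCH
            options.append(s + best(i + 1, j + 1, 0))
        if i < len(a):
            cost = EXT if state == 1 else OPEN
            options.append(cost + best(i + 1, j, 1))
        if j < len(b):
            cost = EXT if state == 2 else OPEN
            options.append(cost + best(i, j + 1, 2))
        return max(options)

    return best(0, 0, 0)


class TestAlignment:
    def test_identity_case(self):
        aln = cs.align_promoters("ACGT", "ACGT")
        assert aln.a == aln.b == "ACGT"
        assert aln.score == pytest.approx(4.0)

    def test_single_gap_scores_three_matches_plus_open(self):
        aln = cs.align_promoters("ACGT", "AGT")
        assert aln.score == pytest.approx(3 * MATCH + OPEN)  # = -2
        assert aln.a.replace("-", "") == "ACGT"
        assert aln.b.replace("-", "") == "AGT"
        assert aln.ncols == 4 and aln.b.count("-") == 1

    def test_degapping_returns_inputs(self):
        aln = cs.align_promoters("ACGTACGGTT", "ACTACGGT")
        assert aln.degapped("a") == "ACGTACGGTT"
        assert aln.degapped("b") == "ACTACGGT"

    def test_optimum_matches_exhaustive_enumeration(self):
        """DP score equals the exhaustive-alignment optimum on short strings."""
        rng = np.random.default_rng(5)
        cases = [("A", "T"), ("AC", "CA"), ("ACG", "AAACG"), ("ACGTA", "TGCAT")]
        for _ in range(60):
            la, lb = rng.integers(1, 6, size=2)
            cases.append(
                (
                    "".join(rng.choice(list("ACGT"), size=la)),
                    "".join(rng.choice(list("ACGT"), size=lb)),
                )
            )
        for a, b in cases:
            aln = cs.align_promoters(a, b)
            assert aln.score == pytest.approx(exhaustive_best_score(a, b)), (a, b)

    def test_alignment_score_consistent_with_rows(self):
        """Rescoring the emitted rows column by column reproduces the score."""
        rng = np.random.default_rng(9)
        for _ in range(20):
            a = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 60)))
            b = "".join(rng.choice(list("ACGT"), size=rng.integers(10, 60)))
            aln = cs.align_promoters(a, b)
            score, in_gap = 0.0, None
            for ca, cb in zip(aln.a, aln.b):
                if ca == "-" or cb == "-":
                    gap_row = "a" if ca == "-" else "b"
                    score += EXT if in_gap == gap_row else OPEN
                    in_gap = gap_row
                else:
                    score += MATCH if ca == cb else MISMATCH
                    in_gap = None
            assert aln.score == pytest.approx(score)

    def test_banded_equals_full_for_similar_sequences(self):
        rng = np.random.default_rng(21)
        a = "".join(rng.choice(list("ACGT"), size=500))
        bl = list(a)
        for i in rng.choice(500, size=25, replace=False):
            bl[i] = "ACGT"[(("ACGT".index(bl[i])) + 1) % 4]
        b = "".join(bl)
        full = cs.align_promoters(a, b)
        banded = cs.align_promoters(a, b, band=30)
        assert banded.score == pytest.approx(full.score)

    def test_all_n_rejected(self):
        with pytest.raises(ValueError):
            cs.align_promoters("NNNN", "ACGT")

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            cs.align_promoters("", "ACGT")


class TestPercentIdentity:
    def test_identical_gapless_range(self):
        aln = cs.align_promoters("A" * 50 + "C" * 50, "A" * 50 + "C" * 50)
        assert cs.percent_identity(aln) == pytest.approx(100.0)

    def test_half_matches(self):
        aln = cs.PromoterAlignment("A" * 100, "A" * 50 + "G" * 50, 0.0)
        assert cs.percent_identity(aln) == pytest.approx(50.0)

    def test_gap_columns_count_in_denominator(self):
        # 95 matches, 3 mismatches, 2 gap columns -> 95 / 100 = 95.0
        a = "A" * 95 + "CCC" + "GG"
        b = "A" * 95 + "TTT" + "--"
        aln = cs.PromoterAlignment(a, b, 0.0)
        assert cs.percent_identity(aln) == pytest.approx(95.0)

    def test_n_columns_never_match(self):
        aln = cs.PromoterAlignment("ANAN", "ANAN", 0.0)
        assert cs.percent_identity(aln) == pytest.approx(50.0)


def _mutated_pair(rng, length, rate):
    a = rng.choice(list("ACGT"), size=length)
    b = a.copy()
    hit = rng.random(length) < rate
    shift = rng.integers(1, 4, size=length)
    idx = np.array(["ACGT".index(x) for x in a])
    b[hit] = np.array(list("ACGT"))[(idx + shift) % 4][hit]
    return "".join(a), "".join(b)


class TestConservedRegions:
    def test_fully_identical_pair_is_one_full_region(self):
        rng = np.random.default_rng(2)
        s = "".join(rng.choice(list("ACGT"), size=2000))
        aln = cs.align_promoters(s, s, band=10)
        (region,) = cs.extract_conserved_regions(aln)
        assert (region.start, region.end) == (0, 2000)
        assert region.percent_identity == pytest.approx(100.0)

    def test_unrelated_random_pairs_give_no_regions(self):
        """Per-window identity of aligned unrelated sequence sits far below
        80%, so regions should (essentially) never be emitted."""
        rng = np.random.default_rng(17)
        n_regions = 0
        for _ in range(100):
            a = "".join(rng.choice(list("ACGT"), size=2000))
            b = "".join(rng.choice(list("ACGT"), size=2000))
            aln = cs.align_promoters(a, b, band=40)
            n_regions += bool(cs.extract_conserved_regions(aln))
        assert n_regions <= 1

    def test_planted_block_recovered(self):
        """One 500-bp 95%-identity block inside 60%-identity flanks comes
        back as a single region covering >= 90% of the plant."""
        rng = np.random.default_rng(31)
        fa1, fb1 = _mutated_pair(rng, 700, 0.40)
        ca, cb = _mutated_pair(rng, 500, 0.05)
        fa2, fb2 = _mutated_pair(rng, 800, 0.40)
        aln = cs.align_promoters(fa1 + ca + fa2, fb1 + cb + fb2, band=40)
        regions = cs.extract_conserved_regions(aln)
        assert len(regions) == 1
        overlap = min(regions[0].end, 1200) - max(regions[0].start, 700)
        assert overlap >= 0.9 * 500

    def test_every_region_revalidates_above_threshold(self):
        """Independent recount from the raw alignment exceeds min_identity."""
        rng = np.random.default_rng(77)
        for _ in range(10):
            a, b = _mutated_pair(rng, 3000, rng.uniform(0.05, 0.3))
            aln = cs.align_promoters(a, b, band=20)
            for r in cs.extract_conserved_regions(aln):
                cols = aln.match_mask[r.col_start : r.col_end]
                recount = 100.0 * cols.sum() / cols.size
                assert recount > 80.0
                assert recount == pytest.approx(r.percent_identity)

    def test_total_conserved_bp_monotone_in_min_identity(self):
        rng = np.random.default_rng(4)
        a, b = _mutated_pair(rng, 3000, 0.15)
        aln = cs.align_promoters(a, b, band=20)
        totals = []
        for min_id in (70.0, 80.0, 90.0, 95.0):
            regions = cs.extract_conserved_regions(aln, min_identity=min_id)
            totals.append(sum(r.length_bp for r in regions))
        assert totals == sorted(totals, reverse=True)

    def test_window_longer_than_alignment_uses_whole_alignment(self):
        aln = cs.align_promoters("ACGTACGTAC", "ACGTACGTAC")
        (region,) = cs.extract_conserved_regions(
            aln, window_bp=100, min_region_bp=5
        )
        assert (region.start, region.end) == (0, 10)

    def test_swap_symmetry_total_columns(self):
        rng = np.random.default_rng(50)
        a, b = _mutated_pair(rng, 2000, 0.1)
        ra = cs.extract_conserved_regions(cs.align_promoters(a, b, band=20))
        rb = cs.extract_conserved_regions(cs.align_promoters(b, a, band=20))
        tot_a = sum(r.col_end - r.col_start for r in ra)
        tot_b = sum(r.col_end - r.col_start for r in rb)
        assert abs(tot_a - tot_b) <= 100  # within gap-placement tie effects
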