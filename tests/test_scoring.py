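"""Scoring primitives: pair scores, measures, partition<->haplotype maps."""

from fractions import Fraction

import numpy as np
import pytest

from conftest import random_haplotype, random_matrix
from hapbop.scoring import (
    HaplotypePair,
    Partition,
    assigned_errors,
    conflict,
    cut_score,
    errors_corrected,
    fragment_weight,
    haplotype_from_partition,
    pair_weight,
    partition_from_haplotype,
    partition_score,
)
from hapbop.snp_matrix import GAP, SnpMatrix

ZERO, ONE = 0, 1


def brute_errors_corrected(hap, M):
    """Independent re-implementation: explicit per-row, per-haplotype loops."""
    total = 0
    for i in range(M.m):
        per_h = []
        for h in (hap.h1, hap.h2):
            c = 0
            for j in range(M.n):
                a = int(M.data[i, j])
                if a != GAP and a != int(h[j]):
                    c += 1
            per_h.append(c)
        total += min(per_h)
    return total


def brute_cut_score(part, M):
    """Explicit O(m^2 n) pair loop over the weighted complete fragment graph."""
    asg = part.assignment
    total = 0
    for a in range(M.m):
        for b in range(a + 1, M.m):
            if asg[a] == asg[b]:
                continue
            for j in range(M.n):
                x, y = int(M.data[a, j]), int(M.data[b, j])
                if x == GAP or y == GAP:
                    continue
                total += 1 if x != y else -1
    return total


class TestPairScores:
    @pytest.mark.parametrize(
        "a, b, expected",
        [(ZERO, ONE, 1), (GAP, ONE, 0), (ONE, ONE, 0), (ZERO, ZERO, 0), (ONE, GAP, 0), (GAP, GAP, 0)],
    )
    def test_conflict_table(self, a, b, expected):
        assert conflict(a, b) == expected

    @pytest.mark.parametrize(
        "a, b, expected",
        [(ZERO, ZERO, -1), (ZERO, ONE, 1), (GAP, ZERO, 0), (ONE, ONE, -1), (ONE, ZERO, 1), (ONE, GAP, 0)],
    )
    def test_pair_weight_table(self, a, b, expected):
        assert pair_weight(a, b) == expected

    def test_fragment_weight_examples(self):
        M = SnpMatrix.from_strings(["01-", "011"])
        assert fragment_weight(M.data[0], M.data[1]) == -2
        N = SnpMatrix.from_strings(["00", "11"])
        assert fragment_weight(N.data[0], N.data[1]) == 2
        assert fragment_weight(N.data[0], N.data[0]) == -2  # -L for gap-free self

    def test_fragment_weight_is_summed_pair_weight(self, rng):
        for _ in range(20):
            M = random_matrix(rng, 2, 12, gap_rate=0.3)
            expected = sum(
                pair_weight(int(a), int(b)) for a, b in zip(M.data[0], M.data[1])
            )
            assert fragment_weight(M.data[0], M.data[1]) == expected

    def test_length_mismatch_raises(self):
        with pytest.raises(ValueError):
            fragment_weight(np.array([0, 1], dtype=np.int8), np.array([0], dtype=np.int8))


class TestErrorsCorrected:
    def test_error_free(self):
        M = SnpMatrix.from_strings(["00", "11"])
        assert errors_corrected(HaplotypePair.from_strings("00", "11"), M) == 0

    def test_one_off_row(self):
        M = SnpMatrix.from_strings(["00", "01"])
        assert errors_corrected(HaplotypePair.from_strings("00", "11"), M) == 1

    def test_matches_brute_force(self, rng):
        for _ in range(25):
            M = random_matrix(rng, 6, 8)
            H = random_haplotype(rng, 8)
            assert errors_corrected(H, M) == brute_errors_corrected(H, M)

    def test_dimension_mismatch(self):
        M = SnpMatrix.from_strings(["00"])
        with pytest.raises(ValueError):
            errors_corrected(HaplotypePair.from_strings("000", "111"), M)


class TestCutScore:
    def test_split_pair(self):
        M = SnpMatrix.from_strings(["00", "11"])
        assert cut_score(Partition((0, 1), (0, 1)), M) == 2

    def test_same_group_no_cross_pairs(self):
        M = SnpMatrix.from_strings(["00", "11"])
        assert cut_score(Partition((0, 1), (0, 0)), M) == 0

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(25):
            M = random_matrix(rng, 6, 8)
            groups = tuple(int(g) for g in rng.integers(0, 2, M.m))
            P = Partition(tuple(range(M.m)), groups)
            assert cut_score(P, M) == brute_cut_score(P, M)

    def test_partial_partition_rejected(self):
        M = SnpMatrix.from_strings(["00", "11"])
        with pytest.raises(ValueError):
            cut_score(Partition((0,), (0,)), M)


class TestPartitionScore:
    def test_hand_example(self):
        M = SnpMatrix.from_strings(["00", "11"])
        s = partition_score(Partition((0, 1), (0, 1)), M, 0.1)
        assert (s.errors_corrected, s.fragments_cut) == (0, 2)
        assert s.partition_score == pytest.approx(-0.2)
        assert s.w == Fraction(1, 10)

    def test_complement_symmetry(self, rng):
        for _ in range(25):
            M = random_matrix(rng, 6, 8)
            groups = tuple(int(g) for g in rng.integers(0, 2, M.m))
            P = Partition(tuple(range(M.m)), groups)
            a = partition_score(P, M, 0.1)
            b = partition_score(P.complemented(), M, 0.1)
            assert (a.errors_corrected, a.fragments_cut) == (
                b.errors_corrected,
                b.fragments_cut,
            )

    def test_w_zero_bounds_induced_haplotype_errors(self, rng):
        # the partition measure counts each fragment against its own group's
        # haplotype; letting fragments defect can only reduce the count
        for _ in range(25):
            M = random_matrix(rng, 6, 8)
            groups = tuple(int(g) for g in rng.integers(0, 2, M.m))
            P = Partition(tuple(range(M.m)), groups)
            s = partition_score(P, M, 0)
            assert s.errors_corrected == assigned_errors(P, M)
            hp = haplotype_from_partition(P, M)
            assert s.partition_score >= errors_corrected(hp, M)

    def test_score_key_matches_exact_arithmetic(self, rng):
        for w in (0, 0.1, 0.25, 1):
            M = random_matrix(rng, 5, 6)
            P = Partition(tuple(range(M.m)), tuple([0] * M.m))
            s = partition_score(P, M, w)
            assert s.score_key() == s.exact_score * Fraction(str(w)).denominator


class TestHaplotypeFromPartition:
    def test_count_rule(self):
        M = SnpMatrix.from_strings(["00", "01", "11"])
        H = haplotype_from_partition(Partition((0, 1, 2), (0, 0, 1)), M)
        assert "".join(map(str, H.h1)) == "00"
        assert "".join(map(str, H.h2)) == "11"
        assert H.phased.all()

    def test_tie_gets_zero_allele_but_unphased(self):
        # at column 1 the two groups hold one '0' each: the vote is balanced
        # (N11+N20 = N10+N21 = 1), so the data cannot orient the site
        M = SnpMatrix.from_strings(["00", "01"])
        H = haplotype_from_partition(Partition((0, 1), (0, 1)), M)
        assert H.h1[0] == 0  # the <= branch
        assert not H.phased[0]
        assert H.phased[1]

    def test_empty_column_unphased(self):
        M = SnpMatrix.from_strings(["0-0", "1-1"])
        H = haplotype_from_partition(Partition((0, 1), (0, 1)), M)
        assert not H.phased[1]
        assert H.phased[0] and H.phased[2]


class TestPartitionFromHaplotype:
    def test_clean_split(self):
        M = SnpMatrix.from_strings(["00", "11"])
        P = partition_from_haplotype(HaplotypePair.from_strings("00", "11"), M)
        assert P.groups == (0, 1)

    def test_tie_goes_to_group_two(self):
        M = SnpMatrix.from_strings(["00-", "0-1"])
        P = partition_from_haplotype(HaplotypePair.from_strings("000", "111"), M)
        assert P.groups == (0, 1)  # row 1 ties (1 conflict each) -> group 1

    def test_theorem_one_round_trip_never_increases_errors(self, rng):
        for _ in range(50):
            M = random_matrix(rng, int(rng.integers(2, 9)), int(rng.integers(3, 11)))
            H = random_haplotype(rng, M.n)
            P = partition_from_haplotype(H, M)
            H2 = haplotype_from_partition(P, M)
            assert errors_corrected(H, M) >= errors_corrected(H2, M)


class TestPairScoreProperties:
    """Algebraic relations between the two pair scores (property-based)."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    allele = st.sampled_from([ZERO, ONE, GAP])

    @given(a=allele, b=allele)
    @settings(derandomize=True, max_examples=50)
    def test_conflict_is_positive_part_of_pair_weight(self, a, b):
        assert conflict(a, b) == max(pair_weight(a, b), 0)

    @given(a=allele, b=allele)
    @settings(derandomize=True, max_examples=50)
    def test_pair_scores_symmetric(self, a, b):
        assert pair_weight(a, b) == pair_weight(b, a)
        assert conflict(a, b) == conflict(b, a)

    @given(rows=st.lists(st.text(alphabet="01-", min_size=4, max_size=4), min_size=2, max_size=6))
    @settings(derandomize=True, max_examples=50)
    def test_fragment_weight_consistent_with_pairs(self, rows):
        M = SnpMatrix.from_strings(rows)
        got = fragment_weight(M.data[0], M.data[1])
        assert got == sum(
            pair_weight(int(a), int(b)) for a, b in zip(M.data[0], M.data[1])
        )


class TestPartitionCanonicalForm:
    def test_smallest_row_in_group_zero(self):
        P = Partition.from_assignment({3: 1, 5: 0, 7: 1})
        assert P.groups[0] == 0
        assert P.assignment == {3: 0, 5: 1, 7: 0}

    def test_complement_is_same_bipartition(self):
        P = Partition((0, 1, 2), (0, 1, 0))
        assert P.complemented().canonical() == P
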