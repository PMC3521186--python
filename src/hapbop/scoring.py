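"""Scoring primitives of the balanced-partition haplotyping model.

A bipartition P = (G1, G2) of the fragments induces a haplotype pair by
per-column majority vote, and is judged by two measures:

* ``sc`` (errors corrected): the minimum number of allele calls that must be
  flipped for every fragment to match one of the two induced haplotypes —
  the classic minimum-error-correction objective;
* ``sd`` (fragments cut): the total pairwise agreement/disagreement weight
  across the cut of the fragment conflict graph — the maximum-fragments-cut
  objective.

The combined partition score is ``sp = sc - w * sd`` with weight factor
``w >= 0``; minimising sp at w=0 recovers pure error correction, while a
large w approaches a pure max-cut.  Scores are kept in exact arithmetic:
sc and sd are integers and w is held as a `fractions.Fraction`, so score
comparisons never hinge on float rounding.
"""

from __future__ import annotations

from dataclasses import dataclass
from fractions import Fraction

import numpy as np

from .snp_matrix import GAP, SnpMatrix


def as_fraction(w: float | int | str | Fraction) -> Fraction:
    """Normalise a weight factor to an exact Fraction (0.1 -> 1/10)."""
    if isinstance(w, Fraction):
        f = w
    else:
        f = Fraction(str(w))
    if f < 0:
        raise ValueError("weight factor w must be non-negative")
    return f


# -- elementary pair scores (Eq-level primitives) --------------------------


def conflict(a: int, b: int) -> int:
    """1 iff both alleles are called and disagree, else 0."""
    return int(a != GAP and b != GAP and a != b)


def pair_weight(a: int, b: int) -> int:
    """-1 if called and equal, +1 if called and unequal, 0 if either is a gap."""
    if a == GAP or b == GAP:
        return 0
    return 1 if a != b else -1


def fragment_weight(f1: np.ndarray, f2: np.ndarray) -> int:
    """Summed pair weight between two fragment rows (their graph edge weight)."""
    f1 = np.asarray(f1, dtype=np.int8)
    f2 = np.asarray(f2, dtype=np.int8)
    if f1.shape != f2.shape:
        raise ValueError("fragment length mismatch")
    both = (f1 != GAP) & (f2 != GAP)
    return int(np.sum(both & (f1 != f2))) - int(np.sum(both & (f1 == f2)))


# -- haplotypes and partitions --------------------------------------------


@dataclass
class HaplotypePair:
    """Two complementary haplotypes over {0,1} with per-site phased flags.

    All loci are heterozygous, so ``h2`` is always the bitwise complement of
    ``h1``.  ``phased[j]`` is False where the reconstruction could not
    determine the alleles (no covering fragment, a tied vote, or a singleton
    block).
    """

    h1: np.ndarray
    h2: np.ndarray
    phased: np.ndarray

    def __post_init__(self) -> None:
        self.h1 = np.asarray(self.h1, dtype=np.int8)
        self.h2 = np.asarray(self.h2, dtype=np.int8)
        self.phased = np.asarray(self.phased, dtype=bool)
        if not (self.h1.shape == self.h2.shape == self.phased.shape):
            raise ValueError("haplotype component shapes differ")
        if np.any(self.h1 == self.h2):
            raise ValueError("haplotypes must be complementary at every site")

    @property
    def n(self) -> int:
        return self.h1.shape[0]

    def complement(self) -> "HaplotypePair":
        return HaplotypePair(self.h2.copy(), self.h1.copy(), self.phased.copy())

    @classmethod
    def from_h1(cls, h1, phased=None) -> "HaplotypePair":
        h1 = np.asarray(h1, dtype=np.int8)
        if phased is None:
            phased = np.ones_like(h1, dtype=bool)
        return cls(h1, (1 - h1).astype(np.int8), phased)

    @classmethod
    def from_strings(cls, s1: str, s2: str, phased=None) -> "HaplotypePair":
        h1 = np.array([int(c) for c in s1], dtype=np.int8)
        h2 = np.array([int(c) for c in s2], dtype=np.int8)
        if phased is None:
            phased = np.ones_like(h1, dtype=bool)
        return cls(h1, h2, phased)


@dataclass(frozen=True)
class Partition:
    """Assignment of fragments to group 0 or 1, canonical under complement.

    Complementing every assignment yields the same bipartition, so partitions
    are stored canonically: the smallest row index in the domain is in group
    0.
    """

    rows: tuple[int, ...]
    groups: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.rows) != len(self.groups):
            raise ValueError("rows/groups length mismatch")
        if any(g not in (0, 1) for g in self.groups):
            raise ValueError("groups must be 0 or 1")

    @classmethod
    def from_assignment(cls, assignment: dict[int, int]) -> "Partition":
        rows = tuple(sorted(assignment))
        groups = tuple(assignment[r] for r in rows)
        return cls(rows, groups).canonical()

    def canonical(self) -> "Partition":
        if self.groups and self.groups[0] == 1:
            return Partition(self.rows, tuple(1 - g for g in self.groups))
        return self

    def complemented(self) -> "Partition":
        return Partition(self.rows, tuple(1 - g for g in self.groups))

    @property
    def assignment(self) -> dict[int, int]:
        return dict(zip(self.rows, self.groups))

    def group(self, row: int) -> int:
        return self.groups[self.rows.index(row)]


@dataclass(frozen=True)
class ScoreBreakdown:
    """sc, sd and the combined partition score sp = sc - w*sd."""

    errors_corrected: int
    fragments_cut: int
    w: Fraction

    @property
    def partition_score(self) -> float:
        return float(self.errors_corrected - self.w * self.fragments_cut)

    @property
    def exact_score(self) -> Fraction:
        return Fraction(self.errors_corrected) - self.w * self.fragments_cut

    def score_key(self) -> int:
        """Integer comparison key: den*sc - num*sd (exact, no floats)."""
        return (
            self.w.denominator * self.errors_corrected
            - self.w.numerator * self.fragments_cut
        )


# -- aggregate measures ----------------------------------------------------


def errors_corrected(hap: HaplotypePair, matrix: SnpMatrix) -> int:
    """Minimum-error-correction measure sc(H, M).

    Each fragment is matched to whichever haplotype it conflicts with least;
    the measure is the summed per-fragment minimum conflict count, a lower
    bound on the number of sequencing errors if H were the truth.
    """
    if hap.n != matrix.n:
        raise ValueError("haplotype/matrix dimension mismatch")
    data = matrix.data
    called = data != GAP
    c1 = np.sum(called & (data != hap.h1[None, :]), axis=1)
    c2 = np.sum(called & (data != hap.h2[None, :]), axis=1)
    return int(np.minimum(c1, c2).sum())


def cut_score(partition: Partition, matrix: SnpMatrix) -> int:
    """Fragments-cut measure sd(P, M): summed edge weight across the cut."""
    if set(partition.rows) != set(range(matrix.m)):
        raise ValueError("partition must be total on the matrix rows")
    asg = partition.assignment
    total = 0
    for a in range(matrix.m):
        for b in range(a + 1, matrix.m):
            if asg[a] != asg[b]:
                total += fragment_weight(matrix.data[a], matrix.data[b])
    return total


def group_counts(partition: Partition, matrix: SnpMatrix) -> np.ndarray:
    """N[g, v, j]: fragments in group g with allele v at column j (0-based)."""
    counts = np.zeros((2, 2, matrix.n), dtype=np.int64)
    asg = partition.assignment
    for i in partition.rows:
        row = matrix.data[i]
        g = asg[i]
        for v in (0, 1):
            counts[g, v] += row == v
    return counts


def haplotype_from_partition(partition: Partition, matrix: SnpMatrix) -> HaplotypePair:
    """Majority-vote haplotype induced by a fragment bipartition.

    At column j let N[g, v] count group-g fragments with allele v.  If
    N[1,1]+N[2,0] <= N[1,0]+N[2,1] (1-based group labels) then H1[j]=0, else
    H1[j]=1; H2 is the complement.  The <= makes ties deterministic, but a
    tied vote means the data cannot decide the phase at j, so tied and
    uncovered columns are flagged unphased (their alleles still follow the
    rule so the pair remains well-formed).
    """
    counts = group_counts(partition, matrix)
    vote0 = counts[0, 1] + counts[1, 0]  # evidence against H1[j]=0
    vote1 = counts[0, 0] + counts[1, 1]  # evidence against H1[j]=1
    h1 = (vote0 > vote1).astype(np.int8)
    coverage = counts.sum(axis=(0, 1))
    phased = (coverage > 0) & (vote0 != vote1)
    return HaplotypePair(h1, (1 - h1).astype(np.int8), phased)


def partition_from_haplotype(hap: HaplotypePair, matrix: SnpMatrix) -> Partition:
    """Assign each fragment to the haplotype it conflicts with least.

    Strictly fewer conflicts with h1 puts a fragment in group 0; ties and
    the reverse go to group 1.  The result is canonicalized.
    """
    if hap.n != matrix.n:
        raise ValueError("haplotype/matrix dimension mismatch")
    data = matrix.data
    called = data != GAP
    c1 = np.sum(called & (data != hap.h1[None, :]), axis=1)
    c2 = np.sum(called & (data != hap.h2[None, :]), axis=1)
    groups = (c1 >= c2).astype(int)  # strict-less -> group 0, else group 1
    return Partition(tuple(range(matrix.m)), tuple(int(g) for g in groups)).canonical()


def assigned_errors(partition: Partition, matrix: SnpMatrix) -> int:
    """Errors-corrected measure of a partition (column-wise form).

    Sums, over columns, the minority vote min(N[1,1]+N[2,0], N[1,0]+N[2,1]):
    the number of calls to flip so that every fragment matches the haplotype
    of *its own* group, minimised over the induced haplotype.  This is the
    quantity the dynamic program tracks incrementally.  It upper-bounds
    ``errors_corrected(haplotype_from_partition(P, M), M)`` — which lets each
    fragment defect to the other haplotype — with equality at any optimal
    partition (reassigning fragments to their preferred haplotype can only
    lower the column-wise count).
    """
    counts = group_counts(partition, matrix)
    vote0 = counts[0, 1] + counts[1, 0]
    vote1 = counts[0, 0] + counts[1, 1]
    return int(np.minimum(vote0, vote1).sum())


def partition_score(
    partition: Partition, matrix: SnpMatrix, w: float | Fraction
) -> ScoreBreakdown:
    """Combined partition score sp(P, M) = sc(P, M) - w * sd(P, M).

    ``sc`` is the column-wise errors-corrected measure of the partition
    (:func:`assigned_errors`), ``sd`` the fragments-cut measure.
    """
    wf = as_fraction(w)
    sc = assigned_errors(partition, matrix)
    sd = cut_score(partition, matrix)
    return ScoreBreakdown(sc, sd, wf)
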