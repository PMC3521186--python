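"""Brute-force exact solvers, used as oracles for the beam-search heuristic.

These enumerate the full solution space — all 2^(m-1) canonical fragment
bipartitions, or all 2^(n-1) haplotype pairs — and are deliberately written
as plain loops over the scoring primitives, with no shortcuts shared with
the dynamic-programming solver.  Hard caps keep them honest: callers get a
refusal, never a silent truncation.
"""

from __future__ import annotations

from fractions import Fraction

import numpy as np

from .scoring import (
    HaplotypePair,
    Partition,
    ScoreBreakdown,
    as_fraction,
    errors_corrected,
    partition_score,
)
from .snp_matrix import SnpMatrix


class InstanceTooLarge(ValueError):
    """Raised when an instance exceeds the brute-force enumeration cap."""


def exact_bop(
    matrix: SnpMatrix, w: float | Fraction, max_rows: int = 20
) -> tuple[Partition, ScoreBreakdown]:
    """Minimum-partition-score solution by exhaustive enumeration.

    Enumerates every canonical bipartition (row 0 pinned to group 0, so
    2^(m-1) candidates) and returns the minimiser; among equal scores the
    smallest binary encoding (bit i-1 = group of row i) wins.
    """
    wf = as_fraction(w)
    m = matrix.m
    if m > max_rows:
        raise InstanceTooLarge(
            f"exact_bop refuses m={m} rows (cap {max_rows}); raise max_rows explicitly"
        )
    if m == 0:
        return Partition((), ()), ScoreBreakdown(0, 0, wf)
    best: tuple[Partition, ScoreBreakdown] | None = None
    best_key: int | None = None
    for code in range(2 ** (m - 1)):
        groups = (0,) + tuple((code >> b) & 1 for b in range(m - 1))
        part = Partition(tuple(range(m)), groups)
        score = partition_score(part, matrix, wf)
        key = score.score_key()
        if best_key is None or key < best_key:
            best, best_key = (part, score), key
    assert best is not None
    return best


def exact_mec(
    matrix: SnpMatrix, max_cols: int = 20
) -> tuple[HaplotypePair, int]:
    """Minimum-error-correction optimum by enumerating all haplotype pairs.

    All loci are heterozygous, so a haplotype pair is determined by h1 with
    h1[0] pinned to 0 (complement symmetry): 2^(n-1) candidates.  Returns a
    minimiser of the summed per-fragment best-match conflict count.
    """
    n = matrix.n
    if n > max_cols:
        raise InstanceTooLarge(
            f"exact_mec refuses n={n} columns (cap {max_cols}); raise max_cols explicitly"
        )
    best_hap: HaplotypePair | None = None
    best_sc: int | None = None
    for code in range(2 ** max(n - 1, 0)):
        h1 = np.zeros(n, dtype=np.int8)
        for b in range(n - 1):
            h1[b + 1] = (code >> b) & 1
        hap = HaplotypePair.from_h1(h1)
        sc = errors_corrected(hap, matrix)
        if best_sc is None or sc < best_sc:
            best_hap, best_sc = hap, sc
    assert best_hap is not None and best_sc is not None
    return best_hap, best_sc
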