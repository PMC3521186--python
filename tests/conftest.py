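"""Shared fixtures: seeded random-instance generators used across the suite."""

from __future__ import annotations

import numpy as np
import pytest

from hapbop.scoring import HaplotypePair
from hapbop.snp_matrix import SnpMatrix, preprocess, sort_rows


def random_matrix(
    rng: np.random.Generator,
    m: int,
    n: int,
    gap_rate: float = 0.2,
) -> SnpMatrix:
    """Uniformly random m x n matrix over {0,1} with iid gaps, preprocessed.

    Entries are unstructured (maximal noise), so these instances exercise
    the solvers far from the easy error-free regime.  Redraws until at least
    two informative rows and two columns survive preprocessing.
    """
    while True:
        data = rng.integers(0, 2, size=(m, n)).astype(np.int8)
        data[rng.random((m, n)) < gap_rate] = -1
        result = preprocess(SnpMatrix(data))
        if result.matrix.m >= 2 and result.matrix.n >= 2:
            return result.matrix


def random_sorted_matrix(rng, m, n, gap_rate: float = 0.2) -> SnpMatrix:
    return sort_rows(random_matrix(rng, m, n, gap_rate))


def random_haplotype(rng: np.random.Generator, n: int) -> HaplotypePair:
    return HaplotypePair.from_h1(rng.integers(0, 2, size=n).astype(np.int8))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260920)
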