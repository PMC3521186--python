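"""Synthetic fragment generator for benchmarking the phasing model.

The generator emulates aligned sequencing fragments restricted to ``n``
heterozygous SNP loci: a random haplotype pair, ``m`` fragments sampled
evenly from the two haplotypes with normally distributed lengths (mean
``l``, variance 1), per-allele flip errors at rate ``e`` and interior
deletions (gaps) at rate ``g``.  Call coverage ``c`` — total called alleles
over ``n`` — is the derived quantity usually quoted alongside results.

The order of random draws is fixed so a seed pins the dataset bit-exactly:
first the haplotype, then per fragment its length, start, flips (left to
right) and interior deletions (left to right).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import HaplotypePair
from .snp_matrix import GAP, SnpMatrix


@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    n: haplotype length (number of SNP loci), >= 2.
    m: number of fragments; ceil(m/2) are sampled from h1, floor(m/2) from h2.
    l: mean fragment length in SNPs (normal with variance 1, truncated to
       [2, n] by resampling, so every fragment calls at least two sites).
    e: per-allele flip probability (sequencing error rate).
    g: per-interior-allele deletion probability (gap rate); the first and
       last positions of a fragment are never deleted.
    seed: RNG seed; the same seed reproduces the dataset exactly.
    """

    n: int
    m: int
    l: float
    e: float
    g: float
    seed: int

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.m < 2:
            raise ValueError("m must be >= 2")
        if self.l < 2:
            raise ValueError("mean fragment length l must be >= 2")
        if self.l > self.n:
            raise ValueError("mean fragment length l cannot exceed n")
        if not 0 <= self.e <= 1:
            raise ValueError("error rate e must be in [0, 1]")
        if not 0 <= self.g <= 1:
            raise ValueError("gap rate g must be in [0, 1]")


@dataclass
class SimulatedDataset:
    truth: HaplotypePair
    matrix: SnpMatrix
    call_coverage: float
    config: SimulationConfig


def _draw_length(rng: np.random.Generator, l: float, n: int) -> int:
    """round(Normal(l, 1)), redrawn until it lands in [2, n]."""
    while True:
        length = int(round(rng.normal(l, 1.0)))
        if 2 <= length <= n:
            return length


def simulate(config: SimulationConfig) -> SimulatedDataset:
    """Generate one dataset under ``config`` (deterministic given the seed)."""
    rng = np.random.default_rng(config.seed)
    n, m = config.n, config.m
    h1 = rng.integers(0, 2, size=n).astype(np.int8)
    truth = HaplotypePair.from_h1(h1)
    sources = [truth.h1] * ((m + 1) // 2) + [truth.h2] * (m // 2)

    data = np.full((m, n), GAP, dtype=np.int8)
    for i, source in enumerate(sources):
        while True:
            length = _draw_length(rng, config.l, n)
            start = int(rng.integers(0, n - length + 1))
            frag = source[start : start + length].copy()
            flips = rng.random(length) < config.e
            frag = np.where(flips, 1 - frag, frag).astype(np.int8)
            if length > 2:
                dels = rng.random(length - 2) < config.g
                frag[1:-1][dels] = GAP
            if int(np.sum(frag != GAP)) >= 2:
                break
            # a fragment reduced below two calls is resampled, keeping m exact
        data[i, start : start + length] = frag

    matrix = SnpMatrix(data)
    return SimulatedDataset(truth, matrix, coverage(matrix, n), config)


def coverage(matrix: SnpMatrix, n: int) -> float:
    """Average call coverage: total called alleles divided by n."""
    if n <= 0:
        raise ValueError("n must be positive")
    return float(np.sum(matrix.data != GAP)) / n


def write_truth(truth: HaplotypePair, path) -> None:
    """Write a haplotype pair as two lines of 0/1 characters."""
    from pathlib import Path

    lines = [
        "".join(str(int(v)) for v in truth.h1),
        "".join(str(int(v)) for v in truth.h2),
    ]
    Path(path).write_text("\n".join(lines) + "\n")


def read_truth(path) -> HaplotypePair:
    from pathlib import Path

    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) != 2:
        raise ValueError("truth file must contain exactly two haplotype lines")
    return HaplotypePair.from_strings(lines[0], lines[1])
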