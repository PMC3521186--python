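"""Beam-bounded dynamic programming solver for the balanced-partition model.

Rows (fragments) are sorted by span and swept left to right.  The DP state
after row ``i`` is a bipartition of the *active set* R(i) — the sorted rows
that still span column l(i); everything to the left is frozen into the
stored extension.  At most ``k`` candidate states (a beam, organised as a
bounded binary max-heap keyed on score) survive each step; incremental
score updates ``delta_ec``/``delta_fc`` touch only the new row's span and
the active rows, giving O(m * k * k1 * k2) time for maximum span length k1
and maximum active-set size k2.  With ``k >= 2^(k2-1)`` the beam holds every
canonical state and the sweep is exact.
"""

from __future__ import annotations

import heapq
import itertools
from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np

from . import scoring
from .snp_matrix import GAP, Block, SnpMatrix, blocks, is_sorted, sort_rows
from .scoring import HaplotypePair, Partition, ScoreBreakdown, as_fraction


@dataclass(frozen=True)
class SolverConfig:
    """Operating point of the solver.

    ``w`` is the weight factor blending the errors-corrected and
    fragments-cut measures (0 = pure error correction); ``k`` is the beam
    width.  The defaults w=0.1, k=8 are the operating point at which the
    heuristic is both fast and accurate on short-read-like fragments.
    """

    w: float | Fraction = Fraction(1, 10)
    k: int = 8

    def __post_init__(self) -> None:
        object.__setattr__(self, "w", as_fraction(self.w))
        if self.k < 1:
            raise ValueError("beam width k must be >= 1")


@dataclass
class SolverStats:
    """Elementary-operation counters (machine-independent effort measure)."""

    children_generated: int = 0
    heap_inserts: int = 0
    delta_cell_ops: int = 0  # inner-loop (column x active-row) visits

    @property
    def total_ops(self) -> int:
        return self.children_generated + self.heap_inserts + self.delta_cell_ops


@dataclass
class BeamEntry:
    """One candidate state: a canonical partition of the active rows.

    ``active`` is the group vector over the (ascending) active row indices,
    canonical in the sense that its first component is 0.  ``extension`` is
    the full group assignment of all rows seen so far (index -> 0/1, -1 for
    rows not yet assigned); restricted to the active rows it equals
    ``active``.  ``sc``/``sd`` are the exact integer running measures of the
    extension on the rows processed so far.
    """

    active: tuple[int, ...]
    extension: np.ndarray
    sc: int
    sd: int
    order: int = 0

    def key(self, w: Fraction) -> int:
        return w.denominator * self.sc - w.numerator * self.sd


class Beam:
    """Bounded max-heap of beam entries, unique per canonical active state.

    The root is the worst (largest-score) live entry; when the beam is full
    a new entry replaces the root only if strictly better.  Among equal
    scores the earlier-inserted entry survives, which makes the sweep
    deterministic.
    """

    def __init__(self, capacity: int, w: Fraction):
        self.capacity = capacity
        self.w = w
        self._heap: list[list] = []  # [-key, -order, entry] ; max-heap via negation
        self._live: dict[tuple[int, ...], BeamEntry] = {}
        self._counter = itertools.count()
        self.inserts = 0

    def __len__(self) -> int:
        return len(self._live)

    def entries(self) -> list[BeamEntry]:
        return list(self._live.values())

    def _push(self, entry: BeamEntry) -> None:
        entry.order = next(self._counter)
        self._live[entry.active] = entry
        heapq.heappush(self._heap, [-entry.key(self.w), -entry.order, entry])
        self.inserts += 1

    def _root(self) -> BeamEntry:
        # drop stale heap nodes (replaced via dedup) lazily
        while self._heap:
            item = self._heap[0]
            entry = item[2]
            if self._live.get(entry.active) is entry:
                return entry
            heapq.heappop(self._heap)
        raise IndexError("empty beam")

    def insert(self, entry: BeamEntry) -> None:
        existing = self._live.get(entry.active)
        if existing is not None:
            # same canonical state: keep the better score, earlier order wins ties
            if entry.key(self.w) < existing.key(self.w):
                self._push(entry)
            return
        if len(self._live) < self.capacity:
            self._push(entry)
            return
        root = self._root()
        if entry.key(self.w) < root.key(self.w):
            del self._live[root.active]
            self._push(entry)

    def best(self) -> BeamEntry:
        return min(
            self._live.values(), key=lambda e: (e.key(self.w), e.order)
        )


@dataclass
class PhaseResult:
    """Solver output: best partition, induced haplotypes, exact score."""

    partition: Partition
    haplotype: HaplotypePair
    score: ScoreBreakdown
    stats: SolverStats = field(default_factory=SolverStats)

    def __iter__(self):
        return iter((self.partition, self.haplotype, self.score))


# -- incremental score updates --------------------------------------------


def delta_ec(
    matrix: SnpMatrix,
    new_row: int,
    new_group: int,
    carry_rows: list[int],
    groups: np.ndarray,
    stats: SolverStats | None = None,
) -> int:
    """Change in the errors-corrected measure when ``new_row`` joins.

    For every called column j of the new row, the minority vote
    min(N11+N20, N10+N21) over the carried-over active rows is subtracted,
    the new allele is added to its group's tally, and the new minority vote
    added back.  Rows outside the carried set cannot call any column in the
    new row's span (sorted order), so the update is exact.
    """
    row = matrix.data[new_row]
    delta = 0
    for j in np.flatnonzero(row != GAP):
        n = np.zeros((2, 2), dtype=np.int64)
        for l in carry_rows:
            v = matrix.data[l, j]
            if v == GAP:
                continue
            n[groups[l], v] += 1
            if stats is not None:
                stats.delta_cell_ops += 1
        delta -= int(min(n[0, 1] + n[1, 0], n[0, 0] + n[1, 1]))
        n[new_group, row[j]] += 1
        delta += int(min(n[0, 1] + n[1, 0], n[0, 0] + n[1, 1]))
    return delta


def delta_fc(
    matrix: SnpMatrix,
    new_row: int,
    new_group: int,
    carry_rows: list[int],
    groups: np.ndarray,
    stats: SolverStats | None = None,
) -> int:
    """Change in the fragments-cut measure when ``new_row`` joins.

    Only pairs that cross the cut contribute: for each called column of the
    new row and each carried active row in the *other* group calling it,
    -1 for agreement and +1 for disagreement.
    """
    row = matrix.data[new_row]
    delta = 0
    for j in np.flatnonzero(row != GAP):
        a = row[j]
        for l in carry_rows:
            v = matrix.data[l, j]
            if v == GAP:
                continue
            if stats is not None:
                stats.delta_cell_ops += 1
            if groups[l] == new_group:
                continue
            delta += 1 if v != a else -1
    return delta


# -- beam maintenance ------------------------------------------------------


def project_and_dedup(
    beam: Beam, from_rows: list[int], to_rows: list[int], w: Fraction
) -> Beam:
    """Restrict every entry to the surviving active rows and merge duplicates.

    Extensions that agree on the carried-over rows are interchangeable for
    the rest of the sweep, so among them only the best score (earliest on
    ties) is kept.  Restricted partitions are re-canonicalized; when that
    requires complementing, the stored extension is complemented too so the
    invariant (extension restricted to active rows == active) survives.
    """
    out = Beam(beam.capacity, w)
    idx = [from_rows.index(r) for r in to_rows]
    for entry in sorted(beam.entries(), key=lambda e: e.order):
        active = tuple(entry.active[i] for i in idx)
        ext = entry.extension
        if active and active[0] == 1:
            active = tuple(1 - g for g in active)
            ext = np.where(ext >= 0, 1 - ext, ext)
        out.insert(BeamEntry(active, np.asarray(ext), entry.sc, entry.sd))
    return out


def extend_with_row(
    beam: Beam,
    matrix: SnpMatrix,
    new_row: int,
    carry_rows: list[int],
    config: SolverConfig,
    stats: SolverStats,
) -> Beam:
    """Spawn both group placements of ``new_row`` from every beam entry."""
    w = config.w
    out = Beam(config.k, w)
    for entry in sorted(beam.entries(), key=lambda e: e.order):
        for g in (0, 1):
            dc = delta_ec(matrix, new_row, g, carry_rows, entry.extension, stats)
            dd = delta_fc(matrix, new_row, g, carry_rows, entry.extension, stats)
            ext = entry.extension.copy()
            ext[new_row] = g
            active = entry.active + (g,)
            if active[0] == 1:  # only when the carried set is empty
                active = tuple(1 - x for x in active)
                ext = np.where(ext >= 0, 1 - ext, ext)
            child = BeamEntry(active, ext, entry.sc + dc, entry.sd + dd)
            stats.children_generated += 1
            out.insert(child)
    stats.heap_inserts += out.inserts
    return out


# -- the sweep -------------------------------------------------------------


def hbop_phase(
    matrix: SnpMatrix,
    config: SolverConfig | None = None,
    inspect=None,
) -> PhaseResult:
    """Phase a preprocessed, span-sorted SNP matrix.

    Returns the full extension of the best final beam entry, its induced
    haplotype pair and the exact score.  Deterministic given (matrix, w, k).
    ``inspect(i, rows, entries)``, if given, is called after each row ``i``
    is absorbed with the current active rows and live beam entries (used to
    audit the incremental scores against from-scratch recomputation).
    """
    config = config or SolverConfig()
    if matrix.m == 0:
        empty = Partition((), ())
        hap = HaplotypePair(
            np.zeros(matrix.n, dtype=np.int8),
            np.ones(matrix.n, dtype=np.int8),
            np.zeros(matrix.n, dtype=bool),
        )
        return PhaseResult(empty, hap, ScoreBreakdown(0, 0, config.w))
    if not is_sorted(matrix):
        raise ValueError("hbop_phase requires rows sorted by span; use sort_rows")

    spans = matrix.spans()
    stats = SolverStats()
    w = config.w

    beam = Beam(config.k, w)
    ext0 = np.full(matrix.m, -1, dtype=np.int8)
    ext0[0] = 0
    beam.insert(BeamEntry((0,), ext0, 0, 0))
    active_rows = [0]
    if inspect is not None:
        inspect(0, list(active_rows), beam.entries())

    for nxt in range(1, matrix.m):
        l_next = spans[nxt].l
        carry = [r for r in active_rows if spans[r].r >= l_next]
        beam = project_and_dedup(beam, active_rows, carry, w)
        beam = extend_with_row(beam, matrix, nxt, carry, config, stats)
        active_rows = carry + [nxt]
        if inspect is not None:
            inspect(nxt, list(active_rows), beam.entries())

    best = beam.best()
    partition = Partition(
        tuple(range(matrix.m)), tuple(int(g) for g in best.extension)
    ).canonical()
    hap = scoring.haplotype_from_partition(partition, matrix)
    score = ScoreBreakdown(best.sc, best.sd, w)
    return PhaseResult(partition, hap, score, stats)


# -- per-block driver ------------------------------------------------------


@dataclass
class BlockResult:
    block: Block
    partition: Partition | None
    score: ScoreBreakdown | None


@dataclass
class BlockPhaseResult:
    """Per-block solutions plus the assembled genome-wide haplotype pair."""

    haplotype: HaplotypePair
    block_results: list[BlockResult]
    score: ScoreBreakdown
    stats: SolverStats

    @property
    def blocks(self) -> list[Block]:
        return [br.block for br in self.block_results]


def phase_all_blocks(
    matrix: SnpMatrix, config: SolverConfig | None = None
) -> BlockPhaseResult:
    """Phase each connected component independently and assemble the result.

    Fragments calling fewer than two sites are dropped first (they carry no
    phase information); all columns are kept, so coordinates line up with
    the input.  Sites in singleton components are reported unphased, as are
    tied-vote sites inside larger components.  Connected components share no
    fragment, so the per-block scores sum exactly to the whole-matrix score.
    """
    config = config or SolverConfig()
    called = matrix.data != GAP
    keep = np.flatnonzero(called.sum(axis=1) >= 2)
    work = SnpMatrix(
        matrix.data[keep],
        row_ids=[matrix.row_ids[i] for i in keep],
        col_ids=matrix.col_ids,
        qualities=[matrix.qualities[i] for i in keep],
    )

    n = matrix.n
    h1 = np.zeros(n, dtype=np.int8)
    phased = np.zeros(n, dtype=bool)
    total_sc = 0
    total_sd = 0
    stats = SolverStats()
    block_results: list[BlockResult] = []

    for blk in blocks(work):
        if blk.is_singleton:
            block_results.append(BlockResult(blk, None, None))
            continue
        cols = np.array([s - 1 for s in blk.sites])
        sub = SnpMatrix(
            work.data[list(blk.rows)][:, cols],
            row_ids=[work.row_ids[i] for i in blk.rows],
            col_ids=[work.col_ids[c] for c in cols],
        )
        res = hbop_phase(sort_rows(sub), config)
        for local_j, site in enumerate(blk.sites):
            h1[site - 1] = res.haplotype.h1[local_j]
            phased[site - 1] = res.haplotype.phased[local_j]
        total_sc += res.score.errors_corrected
        total_sd += res.score.fragments_cut
        stats.children_generated += res.stats.children_generated
        stats.heap_inserts += res.stats.heap_inserts
        stats.delta_cell_ops += res.stats.delta_cell_ops
        block_results.append(BlockResult(blk, res.partition, res.score))

    hap = HaplotypePair(h1, (1 - h1).astype(np.int8), phased)
    return BlockPhaseResult(
        hap, block_results, ScoreBreakdown(total_sc, total_sd, config.w), stats
    )
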