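"""SNP fragment matrix: data model, fragment-file I/O, preprocessing and blocks.

Aligned sequencing fragments restricted to heterozygous SNP loci are encoded
as an m x n matrix over the alphabet {0, 1, -}: rows are fragments, columns
are SNP sites, '0'/'1' are the two alleles and '-' marks a position the
fragment does not call.  All public column coordinates are 1-based inclusive;
rows use ordinary 0-based Python indices.

Two on-disk dialects are supported:

* ``dense`` -- one fragment per line, ``n`` characters from ``{0,1,-}``;
* ``hapcut`` -- the whitespace-separated format used by HapCUT-family tools:
  ``<num_pieces> <fragment_id> (<start> <allele_string>)+ [<quality_string>]``
  with 1-based piece starts.  Quality strings are retained on read and
  written back, but play no role in scoring (the partition model is
  unweighted).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

#: Internal encoding of the gap symbol '-'.
GAP: int = -1

_CHAR_TO_CODE = {"0": 0, "1": 1, "-": GAP}
_CODE_TO_CHAR = {0: "0", 1: "1", GAP: "-"}

DIALECTS = ("hapcut", "dense")


class FragmentFormatError(ValueError):
    """Raised when a fragment file violates its dialect."""


@dataclass(frozen=True)
class RowSpan:
    """First and last called (non-gap) column of a fragment, 1-based inclusive."""

    l: int
    r: int

    def __post_init__(self) -> None:
        if self.l > self.r:
            raise ValueError(f"invalid span ({self.l}, {self.r})")

    @property
    def length(self) -> int:
        return self.r - self.l + 1


@dataclass(frozen=True)
class Block:
    """A connected component of the SNP-site graph.

    Two sites are joined by an edge when a single fragment calls both, so a
    block is the largest unit within which relative phase is determinable.
    ``sites`` are 1-based column indices in ascending order; ``rows`` are the
    indices of the fragments whose called sites lie in this component.
    """

    sites: tuple[int, ...]
    rows: tuple[int, ...]

    @property
    def is_singleton(self) -> bool:
        return len(self.sites) == 1


class SnpMatrix:
    """An m x n fragment-by-SNP allele matrix over {0, 1, -}.

    Parameters
    ----------
    data:
        Integer array of shape (m, n) with entries in {0, 1, -1}.
    row_ids:
        Stable fragment identifiers (defaults to ``f1..fm``).
    col_ids:
        Original 1-based column coordinates, kept through preprocessing so
        results can be mapped back; defaults to ``1..n``.
    qualities:
        Optional per-row quality strings carried from a hapcut file.
    """

    def __init__(
        self,
        data: np.ndarray | Sequence[Sequence[int]],
        row_ids: Sequence[str] | None = None,
        col_ids: Sequence[int] | None = None,
        qualities: Sequence[str | None] | None = None,
    ) -> None:
        arr = np.asarray(data, dtype=np.int8)
        if arr.ndim != 2:
            arr = arr.reshape(0, 0) if arr.size == 0 else arr
        if arr.ndim != 2:
            raise ValueError("data must be two-dimensional")
        bad = ~np.isin(arr, (0, 1, GAP))
        if bad.any():
            raise ValueError("matrix entries must be 0, 1 or gap (-1)")
        self.data = arr
        self.row_ids = list(row_ids) if row_ids is not None else [
            f"f{i + 1}" for i in range(arr.shape[0])
        ]
        if len(self.row_ids) != arr.shape[0]:
            raise ValueError("row_ids length mismatch")
        self.col_ids = list(col_ids) if col_ids is not None else list(
            range(1, arr.shape[1] + 1)
        )
        if len(self.col_ids) != arr.shape[1]:
            raise ValueError("col_ids length mismatch")
        self.qualities = (
            list(qualities) if qualities is not None else [None] * arr.shape[0]
        )

    # -- basic accessors ---------------------------------------------------

    @property
    def m(self) -> int:
        return self.data.shape[0]

    @property
    def n(self) -> int:
        return self.data.shape[1]

    def row_span(self, i: int) -> RowSpan:
        """Span (l, r) of row ``i`` in 1-based column coordinates."""
        called = np.flatnonzero(self.data[i] != GAP)
        if called.size == 0:
            raise ValueError(f"row {i} has no called alleles")
        return RowSpan(int(called[0]) + 1, int(called[-1]) + 1)

    def spans(self) -> list[RowSpan]:
        return [self.row_span(i) for i in range(self.m)]

    def row_string(self, i: int) -> str:
        return "".join(_CODE_TO_CHAR[int(v)] for v in self.data[i])

    def to_strings(self) -> list[str]:
        return [self.row_string(i) for i in range(self.m)]

    @classmethod
    def from_strings(
        cls, rows: Iterable[str], row_ids: Sequence[str] | None = None
    ) -> "SnpMatrix":
        rows = list(rows)
        if not rows:
            return cls(np.zeros((0, 0), dtype=np.int8), row_ids=[])
        n = len(rows[0])
        if any(len(r) != n for r in rows):
            raise ValueError("all rows must have equal length")
        try:
            data = np.array(
                [[_CHAR_TO_CODE[ch] for ch in r] for r in rows], dtype=np.int8
            )
        except KeyError as exc:
            raise FragmentFormatError(f"invalid allele character {exc}") from exc
        return cls(data, row_ids=row_ids)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SnpMatrix):
            return NotImplemented
        return (
            self.data.shape == other.data.shape
            and bool(np.array_equal(self.data, other.data))
            and self.row_ids == other.row_ids
        )

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"SnpMatrix(m={self.m}, n={self.n})"


# -- I/O -------------------------------------------------------------------


def read_fragments(path: str | Path, dialect: str = "hapcut", n: int | None = None) -> SnpMatrix:
    """Read a fragment file into a :class:`SnpMatrix`.

    ``n`` (total SNP count) may be given for the hapcut dialect; otherwise it
    is inferred as the rightmost column any fragment touches.
    """
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    lines = Path(path).read_text().splitlines()
    if dialect == "dense":
        rows = [ln.strip() for ln in lines if ln.strip()]
        for num, r in enumerate(rows, start=1):
            if set(r) - set("01-"):
                raise FragmentFormatError(
                    f"line {num}: allele outside {{0,1,-}} in {r!r}"
                )
        if rows and len({len(r) for r in rows}) > 1:
            raise FragmentFormatError("dense rows have unequal lengths")
        return SnpMatrix.from_strings(rows)

    pieces_per_row: list[list[tuple[int, str]]] = []
    ids: list[str] = []
    quals: list[str | None] = []
    max_col = n or 0
    for num, ln in enumerate(lines, start=1):
        if not ln.strip():
            continue
        tok = ln.split()
        try:
            npieces = int(tok[0])
        except (ValueError, IndexError):
            raise FragmentFormatError(f"line {num}: cannot parse piece count")
        if len(tok) < 2 + 2 * npieces:
            raise FragmentFormatError(f"line {num}: too few fields for {npieces} pieces")
        frag_id = tok[1]
        pieces: list[tuple[int, str]] = []
        for p in range(npieces):
            try:
                start = int(tok[2 + 2 * p])
            except ValueError:
                raise FragmentFormatError(f"line {num}: bad piece start")
            alleles = tok[3 + 2 * p]
            if set(alleles) - set("01"):
                raise FragmentFormatError(
                    f"line {num}: allele outside {{0,1}} in piece {alleles!r}"
                )
            if start < 1:
                raise FragmentFormatError(f"line {num}: starts are 1-based")
            pieces.append((start, alleles))
            max_col = max(max_col, start + len(alleles) - 1)
        rest = tok[2 + 2 * npieces:]
        qual = rest[0] if rest else None
        covered: set[int] = set()
        for start, alleles in pieces:
            cols = set(range(start, start + len(alleles)))
            if covered & cols:
                raise FragmentFormatError(f"line {num}: overlapping pieces")
            covered |= cols
        pieces_per_row.append(pieces)
        ids.append(frag_id)
        quals.append(qual)

    data = np.full((len(pieces_per_row), max_col), GAP, dtype=np.int8)
    for i, pieces in enumerate(pieces_per_row):
        for start, alleles in pieces:
            for off, ch in enumerate(alleles):
                data[i, start - 1 + off] = _CHAR_TO_CODE[ch]
    return SnpMatrix(data, row_ids=ids, qualities=quals)


def write_fragments(matrix: SnpMatrix, path: str | Path, dialect: str = "hapcut") -> None:
    """Write ``matrix`` so that :func:`read_fragments` round-trips exactly."""
    if dialect not in DIALECTS:
        raise ValueError(f"unknown dialect {dialect!r}")
    out: list[str] = []
    if dialect == "dense":
        out = matrix.to_strings()
    else:
        for i in range(matrix.m):
            row = matrix.data[i]
            pieces: list[tuple[int, str]] = []
            j = 0
            while j < matrix.n:
                if row[j] == GAP:
                    j += 1
                    continue
                k = j
                while k < matrix.n and row[k] != GAP:
                    k += 1
                pieces.append((j + 1, "".join(_CODE_TO_CHAR[int(v)] for v in row[j:k])))
                j = k
            fields = [str(len(pieces)), matrix.row_ids[i]]
            for start, alleles in pieces:
                fields += [str(start), alleles]
            if matrix.qualities[i] is not None:
                fields.append(matrix.qualities[i])
            out.append(" ".join(fields))
    Path(path).write_text("\n".join(out) + ("\n" if out else ""))


# -- preprocessing ---------------------------------------------------------


@dataclass
class PreprocessResult:
    """Preprocessed matrix plus the old->new 1-based column index map."""

    matrix: SnpMatrix
    column_map: dict[int, int] = field(default_factory=dict)
    removed_rows: list[int] = field(default_factory=list)
    removed_columns: list[int] = field(default_factory=list)


def preprocess(matrix: SnpMatrix) -> PreprocessResult:
    """Drop fragments calling <2 sites, then columns left with no coverage.

    Phase is only constrained by fragments linking at least two sites, so
    single-call fragments are uninformative.  Columns that lose all coverage
    are removed and recorded in ``column_map`` (old 1-based -> new 1-based)
    so downstream coordinates remain recoverable.
    """
    called = matrix.data != GAP
    keep_rows = np.flatnonzero(called.sum(axis=1) >= 2)
    removed_rows = [i for i in range(matrix.m) if i not in set(keep_rows.tolist())]
    sub = matrix.data[keep_rows]
    keep_cols = np.flatnonzero((sub != GAP).any(axis=0)) if sub.size else np.array([], dtype=int)
    if matrix.m == 0:
        keep_cols = np.arange(matrix.n)
    column_map = {int(c) + 1: new + 1 for new, c in enumerate(keep_cols)}
    removed_cols = [c + 1 for c in range(matrix.n) if (c + 1) not in column_map]
    new = SnpMatrix(
        sub[:, keep_cols] if sub.size else np.zeros((0, len(keep_cols)), dtype=np.int8),
        row_ids=[matrix.row_ids[i] for i in keep_rows],
        col_ids=[matrix.col_ids[c] for c in keep_cols],
        qualities=[matrix.qualities[i] for i in keep_rows],
    )
    return PreprocessResult(new, column_map, removed_rows, removed_cols)


def sort_rows(matrix: SnpMatrix) -> SnpMatrix:
    """Stable sort of rows by (l, r) span; ties keep input order."""
    spans = matrix.spans()
    order = sorted(range(matrix.m), key=lambda i: (spans[i].l, spans[i].r))
    return SnpMatrix(
        matrix.data[order],
        row_ids=[matrix.row_ids[i] for i in order],
        col_ids=matrix.col_ids,
        qualities=[matrix.qualities[i] for i in order],
    )


def is_sorted(matrix: SnpMatrix) -> bool:
    spans = matrix.spans()
    return all(
        (spans[i].l, spans[i].r) <= (spans[i + 1].l, spans[i + 1].r)
        for i in range(matrix.m - 1)
    )


def active_set(matrix: SnpMatrix, i: int) -> list[int]:
    """Rows among the first i+1 (sorted order) that span column l(i).

    This is the dynamic-programming state support R(i): row ``i`` itself is
    always a member.  Requires sorted rows.
    """
    if not 0 <= i < matrix.m:
        raise IndexError(f"row index {i} out of range")
    spans = matrix.spans()
    li = spans[i].l
    return [j for j in range(i + 1) if spans[j].l <= li <= spans[j].r]


def blocks(matrix: SnpMatrix) -> list[Block]:
    """Connected components of the site graph (edge = co-called by a fragment).

    Components are returned in ascending order of their smallest site; a
    column called by no fragment (or never co-called with another) forms a
    singleton block, which carries no phase information.
    """
    n = matrix.n
    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(a: int, b: int) -> None:
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    row_sites = [np.flatnonzero(matrix.data[i] != GAP) for i in range(matrix.m)]
    for sites in row_sites:
        for a, b in zip(sites[:-1], sites[1:]):
            union(int(a), int(b))

    comp_sites: dict[int, list[int]] = {}
    for c in range(n):
        comp_sites.setdefault(find(c), []).append(c)
    comp_rows: dict[int, list[int]] = {root: [] for root in comp_sites}
    for i, sites in enumerate(row_sites):
        if sites.size:
            comp_rows[find(int(sites[0]))].append(i)
    result = [
        Block(
            sites=tuple(s + 1 for s in sorted(sites)),
            rows=tuple(comp_rows[root]),
        )
        for root, sites in comp_sites.items()
    ]
    result.sort(key=lambda b: b.sites[0])
    return result
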