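"""Partitioning of a data matrix into an N x M grid of blocks.

The block layout drives both the block-wise update rules and the parallel
engine: ``X`` is cut into ``N`` row bands and ``M`` column bands, ``U``
inherits the row bands, ``V`` the column bands, and ``S`` is never
partitioned.

Two partitioners are provided.  For dense matrices the bands are
contiguous and of near-equal dimension (any two band heights differ by at
most one row).  For sparse matrices the bands are chosen by prefix sums of
the per-row (per-column) nonzero counts so each band carries an
approximately equal share of the stored entries — the quantity that
actually determines per-worker load.  Balancing is marginal: rows and
columns are split independently; no joint block-level optimisation and no
row/column reordering is attempted.

All bounds are 0-based, half-open: band ``i`` covers
``rows[bounds[i]:bounds[i+1]]``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

from .model import ConfigurationError, DataMatrix, ShapeError

__all__ = [
    "BlockGrid",
    "partition_dense",
    "partition_sparse",
    "partition_matrix",
    "extract_blocks",
]


@dataclass(frozen=True)
class BlockGrid:
    """Row/column band boundaries of an N x M block layout.

    ``row_bounds`` has ``N + 1`` strictly increasing entries from 0 to
    ``n``; ``col_bounds`` likewise from 0 to ``m``.  ``block_nnz`` is an
    optional ``N x M`` table of per-block nonzero counts, filled when the
    grid was built from (or counted against) a concrete matrix.
    """

    row_bounds: tuple
    col_bounds: tuple
    block_nnz: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        rb = tuple(int(b) for b in self.row_bounds)
        cb = tuple(int(b) for b in self.col_bounds)
        object.__setattr__(self, "row_bounds", rb)
        object.__setattr__(self, "col_bounds", cb)
        for name, bounds in (("row_bounds", rb), ("col_bounds", cb)):
            if len(bounds) < 2 or bounds[0] != 0:
                raise ConfigurationError(f"{name} must start at 0 and define >= 1 band")
            if any(b <= a for a, b in zip(bounds, bounds[1:])):
                raise ConfigurationError(f"{name} must be strictly increasing")

    @property
    def N(self) -> int:
        return len(self.row_bounds) - 1

    @property
    def M(self) -> int:
        return len(self.col_bounds) - 1

    @property
    def n(self) -> int:
        return self.row_bounds[-1]

    @property
    def m(self) -> int:
        return self.col_bounds[-1]

    def row_slices(self) -> List[slice]:
        return [slice(a, b) for a, b in zip(self.row_bounds, self.row_bounds[1:])]

    def col_slices(self) -> List[slice]:
        return [slice(a, b) for a, b in zip(self.col_bounds, self.col_bounds[1:])]

    def to_dict(self) -> dict:
        return {
            "row_bounds": list(self.row_bounds),
            "col_bounds": list(self.col_bounds),
        }


def partition_dense(n: int, m: int, N: int, M: int) -> BlockGrid:
    """Contiguous equal-size N x M grid: ``row_bounds[i] = floor(i*n/N)``.

    Any two row-band heights (and column-band widths) differ by at most 1.
    """
    if not (1 <= N <= n):
        raise ConfigurationError(f"need 1 <= N <= n, got N={N}, n={n}")
    if not (1 <= M <= m):
        raise ConfigurationError(f"need 1 <= M <= m, got M={M}, m={m}")
    row_bounds = tuple(i * n // N for i in range(N + 1))
    col_bounds = tuple(j * m // M for j in range(M + 1))
    return BlockGrid(row_bounds, col_bounds)


def _prefix_sum_bounds(counts: np.ndarray, parts: int, axis_name: str) -> tuple:
    """Split indices into `parts` contiguous bands with ~equal count mass.

    The b-th internal boundary is placed after the first index whose
    cumulative count reaches ``b * total / parts``; boundaries are then
    nudged forward if needed so no band is empty (rows/columns with zero
    count are never dropped — they stay in whichever band their index
    falls into).
    """
    size = counts.size
    if parts > size:
        raise ConfigurationError(
            f"cannot split {size} {axis_name}s into {parts} bands"
        )
    if int(np.count_nonzero(counts)) < parts:
        raise ConfigurationError(
            f"fewer nonempty {axis_name}s than requested bands ({parts})"
        )
    cum = np.cumsum(counts, dtype=np.int64)
    total = int(cum[-1])
    bounds = [0]
    for b in range(1, parts):
        target = b * total / parts
        idx = int(np.searchsorted(cum, target, side="left")) + 1
        idx = max(idx, bounds[-1] + 1)          # no empty band behind us
        idx = min(idx, size - (parts - b))      # leave room for bands ahead
        bounds.append(idx)
    bounds.append(size)
    return tuple(bounds)


def partition_sparse(X: DataMatrix, N: int, M: int) -> BlockGrid:
    """N x M grid balancing nonzero counts per row band and column band."""
    if not X.is_sparse:
        raise ConfigurationError("partition_sparse requires a sparse DataMatrix")
    if not (1 <= N <= X.n) or not (1 <= M <= X.m):
        raise ConfigurationError(
            f"invalid block counts N={N}, M={M} for a {X.n}x{X.m} matrix"
        )
    row_bounds = _prefix_sum_bounds(X.row_nnz(), N, "row")
    col_bounds = _prefix_sum_bounds(X.col_nnz(), M, "column")
    grid = BlockGrid(row_bounds, col_bounds)
    return BlockGrid(row_bounds, col_bounds, block_nnz=count_block_nnz(X, grid))


def partition_matrix(X: DataMatrix, N: int, M: int) -> BlockGrid:
    """Dispatch on storage kind: equal-size bands for dense, nnz-balanced
    bands for sparse."""
    if X.is_sparse:
        return partition_sparse(X, N, M)
    grid = partition_dense(X.n, X.m, N, M)
    return BlockGrid(grid.row_bounds, grid.col_bounds, block_nnz=count_block_nnz(X, grid))


def count_block_nnz(X: DataMatrix, g: BlockGrid) -> np.ndarray:
    """N x M table of nonzero counts per block."""
    if (g.n, g.m) != (X.n, X.m):
        raise ShapeError("grid does not match matrix dimensions")
    table = np.zeros((g.N, g.M), dtype=np.int64)
    if X.is_sparse:
        coo = X.values.tocoo()
        ri = np.searchsorted(g.row_bounds, coo.row, side="right") - 1
        cj = np.searchsorted(g.col_bounds, coo.col, side="right") - 1
        np.add.at(table, (ri, cj), 1)
    else:
        for i, rs in enumerate(g.row_slices()):
            for j, cs in enumerate(g.col_slices()):
                table[i, j] = np.count_nonzero(X.values[rs, cs])
    return table


def extract_blocks(X: DataMatrix, g: BlockGrid):
    """Blocks ``X[(i,j)]`` as a nested list ``blocks[i][j]``.

    Dense blocks are ndarray views; sparse blocks are CSR copies.  Row-
    then-column concatenation of the blocks reconstructs ``X`` exactly.
    """
    if (g.n, g.m) != (X.n, X.m):
        raise ShapeError("grid does not match matrix dimensions")
    blocks = []
    for rs in g.row_slices():
        row = []
        for cs in g.col_slices():
            row.append(X.values[rs, cs])
        blocks.append(row)
    return blocks
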