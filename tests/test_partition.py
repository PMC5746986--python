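"""Block grid construction: equal-size dense bands, nnz-balanced sparse
bands, and exact block round trips."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import blocknmtf as b
from blocknmtf.partition import (
    BlockGrid,
    count_block_nnz,
    extract_blocks,
    partition_dense,
    partition_matrix,
    partition_sparse,
)


class TestPartitionDense:
    @pytest.mark.parametrize(
        "n,m,N,M,rows,cols",
        [
            (4, 4, 2, 2, (0, 2, 4), (0, 2, 4)),
            (5, 3, 2, 1, (0, 2, 5), (0, 3)),
        ],
    )
    def test_floor_formula_examples(self, n, m, N, M, rows, cols):
        g = partition_dense(n, m, N, M)
        assert g.row_bounds == rows and g.col_bounds == cols

    def test_uneven_split_heights(self):
        g = partition_dense(7, 7, 3, 1)
        heights = sorted(np.diff(g.row_bounds))
        assert heights == [2, 2, 3]

    @settings(deadline=None, max_examples=50)
    @given(st.integers(1, 60), st.integers(1, 60), st.data())
    def test_band_spread_at_most_one(self, n, m, data):
        N = data.draw(st.integers(1, n))
        M = data.draw(st.integers(1, m))
        g = partition_dense(n, m, N, M)
        for bounds in (np.diff(g.row_bounds), np.diff(g.col_bounds)):
            assert bounds.max() - bounds.min() <= 1

    def test_too_many_blocks_raises(self):
        with pytest.raises(b.ConfigurationError):
            partition_dense(3, 3, 4, 1)


class TestPartitionSparse:
    def test_prefix_sum_example_by_hand(self):
        # per-row nnz (6, 2, 2, 2): the cumulative count reaches the
        # half-total target 6 already at row 0, so the boundary sits at 1
        rows = np.repeat([0, 1, 2, 3], [6, 2, 2, 2])
        cols = np.concatenate([np.arange(6), [0, 1], [2, 3], [4, 5]])
        X = b.DataMatrix(sp.csr_matrix((np.ones(12), (rows, cols)), shape=(4, 6)))
        assert list(X.row_nnz()) == [6, 2, 2, 2]
        g = partition_sparse(X, 2, 1)
        assert g.row_bounds == (0, 1, 4)

    def test_uniform_nnz_matches_dense_bounds(self):
        X = b.DataMatrix(sp.csr_matrix(np.ones((12, 8))))
        gs = partition_sparse(X, 3, 2)
        gd = partition_dense(12, 8, 3, 2)
        assert gs.row_bounds == gd.row_bounds and gs.col_bounds == gd.col_bounds

    def test_single_block_identity(self):
        X = b.make_skewed_sparse(20, 10, 50, 1.0, seed=0)
        g = partition_sparse(X, 1, 1)
        assert g.row_bounds == (0, 20) and g.col_bounds == (0, 10)

    @pytest.mark.parametrize("seed", range(5))
    def test_balances_skewed_rows_better_than_equal_split(self, seed):
        X = b.make_skewed_sparse(200, 100, 4000, 2.0, seed=seed)
        rn = X.row_nnz()
        gs, gd = partition_sparse(X, 4, 1), partition_dense(200, 100, 4, 1)

        def max_band(g):
            return max(rn[a:c].sum() for a, c in zip(g.row_bounds, g.row_bounds[1:]))

        assert max_band(gs) < max_band(gd)

    def test_fewer_nonempty_rows_than_bands_raises(self):
        X = b.DataMatrix(sp.csr_matrix(np.eye(3, 5)))  # 3 nonempty rows... of 3
        with pytest.raises(b.ConfigurationError):
            partition_sparse(b.DataMatrix(sp.csr_matrix((np.ones(1), ([0], [0])), shape=(4, 4))), 2, 1)
        # requesting as many bands as nonempty rows is still fine
        partition_sparse(X, 3, 1)


class TestExtractBlocks:
    @pytest.mark.parametrize("sparse", [False, True], ids=["dense", "sparse"])
    @pytest.mark.parametrize("N,M", [(1, 1), (2, 2), (3, 2), (2, 3)])
    def test_round_trip_reassembly_is_exact(self, rng, sparse, N, M):
        arr = rng.random((12, 10))
        arr[arr < 0.4] = 0.0
        X = b.DataMatrix(sp.csr_matrix(arr) if sparse else arr)
        g = partition_matrix(X, N, M)
        blocks = extract_blocks(X, g)
        rows = [
            np.hstack([blk.toarray() if sp.issparse(blk) else blk for blk in row])
            for row in blocks
        ]
        assert np.array_equal(np.vstack(rows), arr)

    def test_block_shapes_on_even_grid(self, rng):
        X = b.DataMatrix(rng.random((6, 4)))
        blocks = extract_blocks(X, partition_dense(6, 4, 3, 2))
        assert all(blk.shape == (2, 2) for row in blocks for blk in row)

    def test_block_nnz_table_matches_recount(self, rng):
        arr = rng.random((15, 11))
        arr[arr < 0.5] = 0.0
        for X in (b.DataMatrix(arr), b.DataMatrix(sp.csr_matrix(arr))):
            g = partition_matrix(X, 3, 2)
            table = g.block_nnz if g.block_nnz is not None else count_block_nnz(X, g)
            blocks = extract_blocks(X, g)
            for i, row in enumerate(blocks):
                for j, blk in enumerate(row):
                    direct = blk.nnz if sp.issparse(blk) else np.count_nonzero(blk)
                    assert table[i, j] == direct
            assert table.sum() == X.nnz


class TestBlockGridValidation:
    def test_bounds_must_increase(self):
        with pytest.raises(b.ConfigurationError):
            BlockGrid((0, 3, 3, 6), (0, 4))

    def test_bounds_must_start_at_zero(self):
        with pytest.raises(b.ConfigurationError):
            BlockGrid((1, 4), (0, 2))
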