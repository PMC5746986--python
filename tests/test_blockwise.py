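"""Block-wise updates: the serial-equivalence contract, Gram aggregation
and the 1x1 degeneracy."""

import numpy as np
import pytest
import scipy.sparse as sp

import blocknmtf as b
from blocknmtf.blockwise import (
    aggregate_gram,
    blockwise_iteration,
    fit_blockwise,
)
from blocknmtf.partition import extract_blocks, partition_dense, partition_matrix
from blocknmtf.serial import (
    fit_serial,
    update_s,
    update_s_orth,
    update_u,
    update_u_orth,
    update_v,
    update_v_orth,
)

GRIDS = [(1, 1), (2, 2), (3, 2), (2, 3)]


def split(mat, bounds):
    return [mat[a:c] for a, c in zip(bounds, bounds[1:])]


def one_blockwise_sweep(X, f, cfg, grid):
    blocks = extract_blocks(X, grid)
    U_bands = split(f.U, grid.row_bounds)
    V_bands = split(f.V, grid.col_bounds)
    Ub, Vb, S = blockwise_iteration(blocks, U_bands, V_bands, f.S, cfg)
    return b.FactorTriple(np.vstack(Ub), S, np.vstack(Vb))


class TestAggregateGram:
    def test_equals_whole_factor_gram(self, rng):
        U = rng.random((14, 4))
        bands = split(U, (0, 5, 9, 14))
        assert aggregate_gram(bands) == pytest.approx(U.T @ U, rel=1e-12)

    def test_single_block_is_plain_gram(self, rng):
        U = rng.random((6, 3))
        assert np.array_equal(aggregate_gram([U]), U.T @ U)

    def test_result_symmetric(self, rng):
        g = aggregate_gram(split(rng.random((10, 3)), (0, 4, 10)))
        assert np.max(np.abs(g - g.T)) < 1e-14

    def test_inconsistent_rank_raises(self, rng):
        with pytest.raises(b.ShapeError):
            aggregate_gram([rng.random((3, 2)), rng.random((3, 3))])


class TestSingleSweepEquivalence:
    """One full U->V->S sweep assembled from bands equals the serial sweep."""

    @pytest.mark.parametrize("variant", ["nonorthogonal", "orthogonal"])
    @pytest.mark.parametrize("grid_shape", GRIDS)
    def test_matches_serial_sweep(self, rng, variant, grid_shape):
        X = b.DataMatrix(rng.random((6, 4)))
        cfg = b.FitConfig(k1=2, k2=2, variant=variant)
        f = b.FactorTriple(rng.random((6, 2)), rng.random((2, 2)), rng.random((4, 2)))
        grid = partition_dense(6, 4, *grid_shape)
        got = one_blockwise_sweep(X, f, cfg, grid)

        if variant == "orthogonal":
            U = update_u_orth(X, f, cfg.epsilon)
            f1 = b.FactorTriple(U, f.S, f.V)
            V = update_v_orth(X, f1, cfg.epsilon)
            f2 = b.FactorTriple(U, f.S, V)
            S = update_s_orth(X, f2, cfg.epsilon)
        else:
            U = update_u(X, f, cfg.epsilon)
            f1 = b.FactorTriple(U, f.S, f.V)
            V = update_v(X, f1, cfg.epsilon)
            f2 = b.FactorTriple(U, f.S, V)
            S = update_s(X, f2, cfg.epsilon)
        assert np.max(np.abs(got.U - U)) < 1e-10
        assert np.max(np.abs(got.V - V)) < 1e-10
        assert np.max(np.abs(got.S - S)) < 1e-10

    def test_exact_factorization_stationary_bandwise(self, small_exact):
        X, f = small_exact
        cfg = b.FitConfig(k1=2, k2=2)
        got = one_blockwise_sweep(X, f, cfg, partition_dense(8, 6, 2, 2))
        for a in "USV":
            old, new = getattr(f, a), getattr(got, a)
            assert np.max(np.abs(new - old) / np.maximum(old, 1e-300)) < 1e-12

    def test_zero_entries_stay_zero_bandwise(self, rng):
        U = rng.random((6, 2))
        U[3, 1] = 0.0
        f = b.FactorTriple(U, rng.random((2, 2)), rng.random((4, 2)))
        X = b.DataMatrix(rng.random((6, 4)))
        for variant in ("nonorthogonal", "orthogonal"):
            cfg = b.FitConfig(k1=2, k2=2, variant=variant)
            got = one_blockwise_sweep(X, f, cfg, partition_dense(6, 4, 2, 2))
            assert got.U[3, 1] == 0.0


class TestFitBlockwise:
    def test_one_by_one_grid_bit_identical_to_serial(self, rng):
        arr = rng.random((20, 16))
        for X in (b.DataMatrix(arr), b.DataMatrix(sp.csr_matrix(np.where(arr > 0.5, arr, 0.0)))):
            cfg = b.FitConfig(k1=3, k2=2, seed=4, max_iter=30, tol=0.0)
            rs = fit_serial(X, cfg)
            rb = fit_blockwise(X, cfg, partition_matrix(X, 1, 1))
            for a in "USV":
                assert np.array_equal(getattr(rs.factors, a), getattr(rb.factors, a))
            assert np.array_equal(rs.objective_trajectory, rb.objective_trajectory)

    @pytest.mark.parametrize("variant", ["nonorthogonal", "orthogonal"])
    def test_fifty_iterations_match_serial_on_all_grids(self, variant):
        rng = np.random.default_rng(77)
        X = b.DataMatrix(rng.random((60, 40)))
        cfg = b.FitConfig(k1=5, k2=4, seed=3, max_iter=50, tol=0.0, variant=variant)
        serial = fit_serial(X, cfg)
        for grid_shape in GRIDS:
            res = fit_blockwise(X, cfg, partition_dense(60, 40, *grid_shape))
            for a in "USV":
                diff = np.max(np.abs(getattr(res.factors, a) - getattr(serial.factors, a)))
                assert diff < 1e-8, (grid_shape, a, diff)
            rel = np.abs(res.objective_trajectory - serial.objective_trajectory) / np.maximum(
                serial.objective_trajectory, 1e-300
            )
            assert np.max(rel) < 1e-8

    def test_grid_must_match_matrix(self, rng):
        X = b.DataMatrix(rng.random((10, 8)))
        with pytest.raises(b.ShapeError):
            fit_blockwise(X, b.FitConfig(k1=2, k2=2), partition_dense(9, 8, 2, 2))
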