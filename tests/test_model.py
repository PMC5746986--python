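"""Core types and the Frobenius reconstruction objective."""

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, settings, strategies as st

import blocknmtf as b
from blocknmtf.model import resolve_init_scale


def brute_force_error(X, U, S, V):
    """Independent elementwise double-loop oracle for the objective."""
    R = 0.0
    M = U @ S @ V.T
    for i in range(X.shape[0]):
        for j in range(X.shape[1]):
            R += (X[i, j] - M[i, j]) ** 2
    return R


class TestDataMatrix:
    def test_rejects_negative_dense_with_coordinate(self):
        arr = np.ones((3, 3))
        arr[1, 2] = -0.5
        with pytest.raises(b.ValidationError, match="row 1, column 2"):
            b.DataMatrix(arr)

    def test_rejects_negative_sparse_with_coordinate(self):
        mat = sp.csr_matrix(np.array([[0.0, 1.0], [-2.0, 0.0]]))
        with pytest.raises(b.ValidationError, match="row 1, column 0"):
            b.DataMatrix(mat)

    def test_nnz_counts_strictly_positive_entries(self):
        X = b.DataMatrix(np.array([[0.0, 1.0, 2.0], [0.0, 0.0, 3.0]]))
        assert X.nnz == 3
        # explicit zeros in sparse storage are not counted
        coo = sp.coo_matrix(([1.0, 0.0, 2.0], ([0, 0, 1], [0, 1, 2])), shape=(2, 3))
        assert b.DataMatrix(coo).nnz == 2

    def test_marginal_nnz(self):
        arr = np.array([[1.0, 0.0], [2.0, 3.0]])
        for X in (b.DataMatrix(arr), b.DataMatrix(sp.csr_matrix(arr))):
            assert list(X.row_nnz()) == [1, 2]
            assert list(X.col_nnz()) == [2, 1]


class TestReconstructionError:
    def test_exact_factorization_is_zero(self, small_exact):
        X, f = small_exact
        assert b.reconstruction_error(X, f) == pytest.approx(0.0, abs=1e-20)

    def test_scalar_case(self):
        X = b.DataMatrix([[2.0]])
        f = b.FactorTriple([[1.0]], [[1.0]], [[1.0]])
        assert b.reconstruction_error(X, f) == pytest.approx(1.0)

    def test_matches_brute_force_oracle(self, rng):
        X = rng.random((5, 4))
        U, S, V = rng.random((5, 2)), rng.random((2, 3)), rng.random((4, 3))
        expected = brute_force_error(X, U, S, V)
        got = b.reconstruction_error(b.DataMatrix(X), b.FactorTriple(U, S, V))
        assert got == pytest.approx(expected, rel=1e-10)

    def test_sparse_path_matches_dense_path(self, rng):
        X = rng.random((30, 20))
        X[X < 0.6] = 0.0
        f = b.FactorTriple(rng.random((30, 3)), rng.random((3, 2)), rng.random((20, 2)))
        dense = b.reconstruction_error(b.DataMatrix(X), f)
        sparse = b.reconstruction_error(b.DataMatrix(sp.csr_matrix(X)), f)
        assert sparse == pytest.approx(dense, rel=1e-9)

    @settings(deadline=None, max_examples=25)
    @given(st.integers(0, 10_000), st.floats(0.01, 100.0))
    def test_invariant_under_u_s_rescaling(self, seed, c):
        rng = np.random.default_rng(seed)
        X = b.DataMatrix(rng.random((7, 5)))
        f = b.FactorTriple(rng.random((7, 3)), rng.random((3, 2)), rng.random((5, 2)))
        g = b.FactorTriple(f.U * c, f.S / c, f.V)
        assert b.reconstruction_error(X, g) == pytest.approx(
            b.reconstruction_error(X, f), rel=1e-9
        )

    def test_shape_mismatch_raises(self, rng):
        X = b.DataMatrix(rng.random((4, 4)))
        f = b.FactorTriple(rng.random((5, 2)), rng.random((2, 2)), rng.random((4, 2)))
        with pytest.raises(b.ShapeError):
            b.reconstruction_error(X, f)


class TestInitFactors:
    def test_seeded_reproducibility_and_seed_sensitivity(self):
        cfg = b.FitConfig(k1=3, k2=2, seed=5)
        f1 = b.init_factors(10, 8, cfg)
        f2 = b.init_factors(10, 8, cfg)
        f3 = b.init_factors(10, 8, cfg.with_(seed=6))
        for a in "USV":
            assert np.array_equal(getattr(f1, a), getattr(f2, a))
        assert not np.array_equal(f1.U, f3.U)

    def test_strict_positivity_and_scale_bound(self):
        cfg = b.FitConfig(k1=2, k2=2, seed=0, init_scale=0.3)
        f = b.init_factors(50, 40, cfg)
        for mat in (f.U, f.S, f.V):
            assert mat.min() > 0
            assert mat.max() <= 0.3

    def test_default_scale_targets_data_magnitude(self, rng):
        X = b.DataMatrix(4.0 * rng.random((20, 20)))
        cfg = b.FitConfig(k1=2, k2=2)
        assert resolve_init_scale(X, cfg) == pytest.approx(np.sqrt(X.mean() / 4))

    def test_invalid_ranks_raise(self):
        with pytest.raises(b.ConfigurationError):
            b.FitConfig(k1=0, k2=2)
        with pytest.raises(b.ConfigurationError):
            b.init_factors(3, 3, b.FitConfig(k1=5, k2=2))


class TestFitConfig:
    def test_rank_bound_against_matrix(self, rng):
        X = b.DataMatrix(rng.random((6, 4)))
        with pytest.raises(b.ConfigurationError):
            b.FitConfig(k1=5, k2=2).validate_for(X)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_iter": 0},
            {"tol": -1.0},
            {"epsilon": 0.0},
            {"check_every": 0},
            {"variant": "qr"},
        ],
    )
    def test_invalid_settings_raise(self, kwargs):
        with pytest.raises(b.ConfigurationError):
            b.FitConfig(k1=2, k2=2, **kwargs)
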