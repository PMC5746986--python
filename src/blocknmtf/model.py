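"""Core types and the reconstruction-error objective for non-negative
matrix tri-factorization (NMTF).

NMTF decomposes a non-negative data matrix ``X`` (``n`` instances by ``m``
features) into three non-negative latent factors,

.. math::

    X \\approx U S V^T,

with ``U`` of shape ``(n, k1)``, ``S`` of shape ``(k1, k2)`` and ``V`` of
shape ``(m, k2)``.  Columns of ``U`` and ``V`` are latent vectors spanning
the row and column spaces of ``X``; ``S`` maps interactions between the two
latent spaces, which makes the model suitable for non-square matrices and
for co-clustering.  The factors are learned by minimising the squared
Frobenius reconstruction error

.. math::

    F(U, S, V) = \\lVert X - U S V^T \\rVert_{Fro}^2 .

This module holds the shared domain types (:class:`DataMatrix`,
:class:`FactorTriple`, :class:`FitConfig`, :class:`FitResult`), the
objective :func:`reconstruction_error`, and seeded factor initialisation.
All numerics are double precision.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Union

import numpy as np
import scipy.sparse as sp

__all__ = [
    "BlockNMTFError",
    "ShapeError",
    "ConfigurationError",
    "ValidationError",
    "NumericalError",
    "DataMatrix",
    "FactorTriple",
    "FitConfig",
    "FitResult",
    "reconstruction_error",
    "init_factors",
    "resolve_init_scale",
]


class BlockNMTFError(Exception):
    """Base class for all package errors."""


class ShapeError(BlockNMTFError, ValueError):
    """Inconsistent matrix/factor dimensions."""


class ConfigurationError(BlockNMTFError, ValueError):
    """Invalid ranks, block counts, tolerances or other settings."""


class ValidationError(BlockNMTFError, ValueError):
    """Input data violates a model requirement (e.g. negative entries)."""


class NumericalError(BlockNMTFError, RuntimeError):
    """Non-finite values encountered during factorisation."""


def _as_float64_dense(values: np.ndarray) -> np.ndarray:
    arr = np.asarray(values, dtype=np.float64)
    if arr.ndim != 2:
        raise ShapeError(f"expected a 2-D array, got ndim={arr.ndim}")
    return arr


class DataMatrix:
    """A non-negative data matrix with a dense or sparse storage tag.

    Parameters
    ----------
    values
        Either a 2-D :class:`numpy.ndarray` (dense storage) or any scipy
        sparse matrix (converted to CSR, sparse storage).  All entries
        must be ``>= 0``.

    Notes
    -----
    ``nnz`` counts entries strictly greater than zero; explicitly stored
    zeros in a sparse input are eliminated so the bookkeeping is exact.
    """

    def __init__(self, values: Union[np.ndarray, sp.spmatrix, sp.sparray]):
        if sp.issparse(values):
            mat = sp.csr_matrix(values, dtype=np.float64, copy=True)
            mat.eliminate_zeros()
            if mat.nnz and mat.data.min() < 0:
                coo = mat.tocoo()
                k = int(np.argmin(coo.data))
                raise ValidationError(
                    f"negative entry {coo.data[k]} at row {coo.row[k]}, "
                    f"column {coo.col[k]}"
                )
            self._values: Union[np.ndarray, sp.csr_matrix] = mat
            self._storage = "sparse"
        else:
            arr = _as_float64_dense(values)
            if arr.size and arr.min() < 0:
                idx = np.unravel_index(int(np.argmin(arr)), arr.shape)
                raise ValidationError(
                    f"negative entry {arr[idx]} at row {idx[0]}, column {idx[1]}"
                )
            self._values = arr
            self._storage = "dense"
        n, m = self._values.shape
        if n < 1 or m < 1:
            raise ShapeError("matrix must have at least one row and one column")

    # -- basic properties -------------------------------------------------
    @property
    def values(self) -> Union[np.ndarray, sp.csr_matrix]:
        return self._values

    @property
    def storage(self) -> Literal["dense", "sparse"]:
        return self._storage  # type: ignore[return-value]

    @property
    def is_sparse(self) -> bool:
        return self._storage == "sparse"

    @property
    def shape(self) -> tuple[int, int]:
        return self._values.shape  # type: ignore[return-value]

    @property
    def n(self) -> int:
        return self._values.shape[0]

    @property
    def m(self) -> int:
        return self._values.shape[1]

    @property
    def nnz(self) -> int:
        if self.is_sparse:
            return int(self._values.nnz)
        return int(np.count_nonzero(self._values))

    def toarray(self) -> np.ndarray:
        if self.is_sparse:
            return self._values.toarray()
        return self._values

    def mean(self) -> float:
        """Mean over all n*m entries (zeros included)."""
        if self.is_sparse:
            return float(self._values.data.sum() / (self.n * self.m))
        return float(self._values.mean())

    def row_nnz(self) -> np.ndarray:
        if self.is_sparse:
            return np.diff(self._values.indptr)
        return np.count_nonzero(self._values, axis=1)

    def col_nnz(self) -> np.ndarray:
        if self.is_sparse:
            return np.asarray(
                self._values.getnnz(axis=0), dtype=np.int64
            )
        return np.count_nonzero(self._values, axis=0)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"DataMatrix({self.n}x{self.m}, {self.storage}, nnz={self.nnz})"


@dataclass(frozen=True)
class FactorTriple:
    """The latent factors ``U`` (n x k1), ``S`` (k1 x k2), ``V`` (m x k2)."""

    U: np.ndarray
    S: np.ndarray
    V: np.ndarray

    def __post_init__(self) -> None:
        U = _as_float64_dense(self.U)
        S = _as_float64_dense(self.S)
        V = _as_float64_dense(self.V)
        object.__setattr__(self, "U", U)
        object.__setattr__(self, "S", S)
        object.__setattr__(self, "V", V)
        if U.shape[1] != S.shape[0] or V.shape[1] != S.shape[1]:
            raise ShapeError(
                f"inconsistent factor shapes U{U.shape}, S{S.shape}, V{V.shape}"
            )
        for name, mat in (("U", U), ("S", S), ("V", V)):
            if mat.size and mat.min() < 0:
                raise ValidationError(f"factor {name} contains negative entries")

    @property
    def n(self) -> int:
        return self.U.shape[0]

    @property
    def m(self) -> int:
        return self.V.shape[0]

    @property
    def k1(self) -> int:
        return self.S.shape[0]

    @property
    def k2(self) -> int:
        return self.S.shape[1]

    def reconstruct(self) -> np.ndarray:
        """Dense model reconstruction ``U S V^T``."""
        return self.U @ self.S @ self.V.T

    def copy(self) -> "FactorTriple":
        return FactorTriple(self.U.copy(), self.S.copy(), self.V.copy())


Variant = Literal["nonorthogonal", "orthogonal"]


@dataclass(frozen=True)
class FitConfig:
    """Settings controlling a factorisation run.

    Attributes
    ----------
    k1, k2
        Factorisation ranks: the number of latent vectors for rows and
        columns.  Both must satisfy ``1 <= k <= min(n, m)`` for the bound
        data matrix; useful models have ``k1, k2 << min(n, m)``.
    variant
        ``"nonorthogonal"`` (plain multiplicative rules) or
        ``"orthogonal"`` (square-root damped rules targeting
        ``U^T U = I`` and ``V^T V = I``).
    max_iter
        Hard iteration cap.
    tol
        Relative objective-change threshold for the convergence heuristic;
        checked every ``check_every`` iterations.
    check_every
        Iterations between objective evaluations.
    seed
        Seed for reproducible initialisation.
    epsilon
        Lower guard applied elementwise to update denominators.
    init_scale
        Upper bound of the uniform initial factor values; ``None`` derives
        ``sqrt(mean(X) / (k1 * k2))`` from the data so the expected initial
        reconstruction is on the scale of ``X``.
    """

    k1: int
    k2: int
    variant: Variant = "nonorthogonal"
    max_iter: int = 200
    tol: float = 1e-5
    check_every: int = 10
    seed: int = 0
    epsilon: float = 1e-12
    init_scale: Optional[float] = None

    def __post_init__(self) -> None:
        if self.k1 < 1 or self.k2 < 1:
            raise ConfigurationError("ranks k1 and k2 must be >= 1")
        if self.variant not in ("nonorthogonal", "orthogonal"):
            raise ConfigurationError(f"unknown variant {self.variant!r}")
        if self.max_iter < 1:
            raise ConfigurationError("max_iter must be >= 1")
        if self.tol < 0:
            raise ConfigurationError("tol must be >= 0")
        if self.check_every < 1:
            raise ConfigurationError("check_every must be >= 1")
        if self.epsilon <= 0:
            raise ConfigurationError("epsilon must be > 0")
        if self.init_scale is not None and self.init_scale <= 0:
            raise ConfigurationError("init_scale must be > 0")

    def validate_for(self, X: DataMatrix) -> None:
        bound = min(X.n, X.m)
        if self.k1 > bound or self.k2 > bound:
            raise ConfigurationError(
                f"ranks ({self.k1}, {self.k2}) exceed min(n, m) = {bound}"
            )

    def with_(self, **kwargs) -> "FitConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a factorisation run."""

    factors: FactorTriple
    objective_trajectory: np.ndarray
    converged: bool
    iterations_run: int
    grid: Optional["object"] = None  # BlockGrid; untyped to avoid a cycle

    def __post_init__(self) -> None:
        traj = np.asarray(self.objective_trajectory, dtype=np.float64)
        object.__setattr__(self, "objective_trajectory", traj)


def reconstruction_error(X: DataMatrix, f: FactorTriple) -> float:
    """Squared Frobenius reconstruction error ``||X - U S V^T||_F^2``.

    For dense storage the residual is formed explicitly.  For sparse
    storage the error is expanded through Gram matrices,

    ``||X||^2 - 2 tr(S^T U^T X V) + tr(U^T U S V^T V S^T)``,

    which never densifies ``X``; cancellation near an exact factorisation
    is clamped at zero.
    """
    if (X.n, X.m) != (f.n, f.m):
        raise ShapeError(
            f"data is {X.n}x{X.m} but factors reconstruct {f.n}x{f.m}"
        )
    if X.is_sparse:
        Xs = X.values
        x_sq = float(Xs.data @ Xs.data)
        uxv = f.U.T @ (Xs @ f.V)
        cross = float(np.sum(uxv * f.S))
        gram_u = f.U.T @ f.U
        gram_v = f.V.T @ f.V
        model_sq = float(np.sum(((gram_u @ f.S) @ gram_v) * f.S))
        return max(x_sq - 2.0 * cross + model_sq, 0.0)
    R = X.values - f.reconstruct()
    return float(np.sum(R * R))


def resolve_init_scale(X: DataMatrix, cfg: FitConfig) -> float:
    """The initial-value upper bound actually used for a given matrix."""
    if cfg.init_scale is not None:
        return float(cfg.init_scale)
    mean = X.mean()
    if mean <= 0:
        return 1.0
    return float(np.sqrt(mean / (cfg.k1 * cfg.k2)))


def init_factors(
    n: int, m: int, cfg: FitConfig, scale: Optional[float] = None
) -> FactorTriple:
    """Draw strictly positive initial factors, uniform on ``(0, scale]``.

    Strict positivity matters: multiplicative updates can never revive an
    entry that starts at zero.  The draw order (U, then S, then V) is fixed
    so a seed fully determines the triple.
    """
    if scale is None:
        scale = cfg.init_scale if cfg.init_scale is not None else 1.0
    if scale <= 0:
        raise ConfigurationError("initial scale must be > 0")
    if cfg.k1 > min(n, m) or cfg.k2 > min(n, m):
        raise ConfigurationError(
            f"ranks ({cfg.k1}, {cfg.k2}) exceed min(n, m) = {min(n, m)}"
        )
    rng = np.random.default_rng(cfg.seed)
    # 1 - random() lies in (0, 1]; scaling keeps strict positivity.
    U = scale * (1.0 - rng.random((n, cfg.k1)))
    S = scale * (1.0 - rng.random((cfg.k1, cfg.k2)))
    V = scale * (1.0 - rng.random((m, cfg.k2)))
    return FactorTriple(U, S, V)
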