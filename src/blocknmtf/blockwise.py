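"""Block-wise multiplicative update rules.

Given the N x M block layout of ``X`` (row bands of ``U``, column bands of
``V``, un-partitioned ``S``), every serial rule can be rewritten over the
blocks.  The i-th row band of the U numerator ``X V S^T`` is

.. math::

    \\sum_j X^{(i,j)} (V^{(j)} S^T),

and the only global quantities any band update needs are small ``k x k``
aggregates: the Gram sums ``\\sum_i (U^{(i)})^T U^{(i)}`` and
``\\sum_j (V^{(j)})^T V^{(j)}``, the cross term
``\\sum_{i,j} (U^{(i)})^T X^{(i,j)} V^{(j)}`` and, for the orthogonal
variant, ``\\sum_i (U^{(i)})^T P^{(i)}`` where ``P^{(i)}`` is the band
numerator.  This is what makes the formulation parallel-friendly: bands
are updated independently once the aggregates are shared.

Equivalence with the serial path is a hard contract, not an
approximation: assembled block updates equal the serial updates exactly in
real arithmetic, and to tight floating-point tolerance in practice.  The
orthogonal block rules are implemented as the exact block rewriting of the
serial orthogonal rules (band numerator over band times the global
``U``-side aggregate), which keeps that equivalence.

Partial sums are always accumulated in ascending block index (row-major
for the cross term) so results are bit-stable, and a 1x1 grid reproduces
the serial path bit-for-bit.
"""

from __future__ import annotations

from typing import List, Optional, Sequence

import numpy as np

from .model import (
    DataMatrix,
    FactorTriple,
    FitConfig,
    FitResult,
    NumericalError,
    ShapeError,
    init_factors,
    reconstruction_error,
    resolve_init_scale,
)
from .partition import BlockGrid, extract_blocks, partition_matrix

__all__ = [
    "aggregate_gram",
    "block_update_u",
    "block_update_v",
    "block_update_s",
    "block_update_u_orth",
    "block_update_v_orth",
    "block_update_s_orth",
    "fit_blockwise",
]


def _ordered_sum(parts: Sequence[np.ndarray]) -> np.ndarray:
    """Sequential left-to-right sum; fixed order keeps results bit-stable."""
    total = parts[0]
    for p in parts[1:]:
        total = total + p
    return total


def aggregate_gram(bands: Sequence[np.ndarray]) -> np.ndarray:
    """Sum of per-band Gram matrices, equal to the whole-factor Gram."""
    k = bands[0].shape[1]
    for b in bands:
        if b.shape[1] != k:
            raise ShapeError("factor bands disagree on the latent dimension")
    return _ordered_sum([b.T @ b for b in bands])


def _guard(den: np.ndarray, eps: float) -> np.ndarray:
    return np.maximum(den, eps)


# ---------------------------------------------------------------------------
# single-band rules (non-orthogonal)
# ---------------------------------------------------------------------------

def block_update_u(
    X_row_blocks: Sequence,
    U_band: np.ndarray,
    S: np.ndarray,
    V_bands: Sequence[np.ndarray],
    gram_v: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Update one row band of U from its row of X blocks.

    numerator: sum_j X^(i,j) (V^(j) S^T); denominator: U^(i) (S gram_v S^T).
    """
    num = _ordered_sum([Xb @ (Vb @ S.T) for Xb, Vb in zip(X_row_blocks, V_bands)])
    den = U_band @ ((S @ gram_v) @ S.T)
    return U_band * num / _guard(den, eps)


def block_update_v(
    X_col_blocks: Sequence,
    V_band: np.ndarray,
    S: np.ndarray,
    U_bands: Sequence[np.ndarray],
    gram_u: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Update one column band of V from its column of X blocks.

    numerator: (sum_i (X^(i,j))^T U^(i)) S; denominator: V^(j) (S^T gram_u S).
    """
    num = _ordered_sum([Xb.T @ Ub for Xb, Ub in zip(X_col_blocks, U_bands)]) @ S
    den = V_band @ ((S.T @ gram_u) @ S)
    return V_band * num / _guard(den, eps)


def block_update_s(
    uxv: np.ndarray,
    S: np.ndarray,
    gram_u: np.ndarray,
    gram_v: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Update S from the three global aggregates."""
    den = (gram_u @ S) @ gram_v
    return S * uxv / _guard(den, eps)


def aggregate_uxv(
    blocks: Sequence[Sequence],
    U_bands: Sequence[np.ndarray],
    V_bands: Sequence[np.ndarray],
) -> np.ndarray:
    """Cross aggregate sum_{i,j} (U^(i))^T X^(i,j) V^(j), row-major order."""
    parts = [
        U_bands[i].T @ (blocks[i][j] @ V_bands[j])
        for i in range(len(U_bands))
        for j in range(len(V_bands))
    ]
    return _ordered_sum(parts)


# ---------------------------------------------------------------------------
# single-band rules (orthogonal)
# ---------------------------------------------------------------------------

def block_update_u_orth(
    U_band: np.ndarray,
    P_band: np.ndarray,
    A: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Orthogonal band update U^(i) ∘ sqrt(P^(i) / (U^(i) A)).

    ``P_band`` is the band numerator sum_j X^(i,j) (V^(j) S^T) and ``A``
    the global aggregate sum_i (U^(i))^T P^(i).
    """
    ratio = P_band / _guard(U_band @ A, eps)
    assert ratio.min() >= 0.0
    return U_band * np.sqrt(ratio)


def block_update_v_orth(
    V_band: np.ndarray,
    Q_band: np.ndarray,
    B: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Orthogonal band update V^(j) ∘ sqrt(Q^(j) / (V^(j) B))."""
    ratio = Q_band / _guard(V_band @ B, eps)
    assert ratio.min() >= 0.0
    return V_band * np.sqrt(ratio)


def block_update_s_orth(
    uxv: np.ndarray,
    S: np.ndarray,
    gram_u: np.ndarray,
    gram_v: np.ndarray,
    eps: float = 1e-12,
) -> np.ndarray:
    """Orthogonal S update: square-root damped version of the plain ratio."""
    den = (gram_u @ S) @ gram_v
    ratio = uxv / _guard(den, eps)
    assert ratio.min() >= 0.0
    return S * np.sqrt(ratio)


# ---------------------------------------------------------------------------
# full block-wise iteration and fit
# ---------------------------------------------------------------------------

def blockwise_iteration(
    blocks: Sequence[Sequence],
    U_bands: List[np.ndarray],
    V_bands: List[np.ndarray],
    S: np.ndarray,
    cfg: FitConfig,
):
    """One full U -> V -> S sweep over the bands; returns updated bands.

    Aggregates are recomputed from the freshest factors at the point each
    rule consumes them, matching the serial data flow exactly.
    """
    eps = cfg.epsilon
    N, M = len(U_bands), len(V_bands)
    if cfg.variant == "orthogonal":
        P = [
            _ordered_sum([blocks[i][j] @ (V_bands[j] @ S.T) for j in range(M)])
            for i in range(N)
        ]
        A = _ordered_sum([U_bands[i].T @ P[i] for i in range(N)])
        U_bands = [block_update_u_orth(U_bands[i], P[i], A, eps) for i in range(N)]
        Q = [
            _ordered_sum([blocks[i][j].T @ U_bands[i] for i in range(N)]) @ S
            for j in range(M)
        ]
        B = _ordered_sum([V_bands[j].T @ Q[j] for j in range(M)])
        V_bands = [block_update_v_orth(V_bands[j], Q[j], B, eps) for j in range(M)]
        uxv = aggregate_uxv(blocks, U_bands, V_bands)
        gram_u = aggregate_gram(U_bands)
        gram_v = aggregate_gram(V_bands)
        S = block_update_s_orth(uxv, S, gram_u, gram_v, eps)
        return U_bands, V_bands, S
    gram_v = aggregate_gram(V_bands)
    U_bands = [
        block_update_u(blocks[i], U_bands[i], S, V_bands, gram_v, eps)
        for i in range(N)
    ]
    gram_u = aggregate_gram(U_bands)
    V_bands = [
        block_update_v([blocks[i][j] for i in range(N)], V_bands[j], S, U_bands, gram_u, eps)
        for j in range(M)
    ]
    uxv = aggregate_uxv(blocks, U_bands, V_bands)
    gram_v = aggregate_gram(V_bands)
    S = block_update_s(uxv, S, gram_u, gram_v, eps)
    return U_bands, V_bands, S


def _split(mat: np.ndarray, bounds) -> List[np.ndarray]:
    return [mat[a:b] for a, b in zip(bounds, bounds[1:])]


def fit_blockwise(
    X: DataMatrix,
    cfg: FitConfig,
    grid: Optional[BlockGrid] = None,
    init: Optional[FactorTriple] = None,
) -> FitResult:
    """Run NMTF through the block-wise rules on the given grid.

    With identical initialisation (same seed) the result matches
    :func:`blocknmtf.serial.fit_serial` to floating-point tolerance on any
    grid, and bit-for-bit on a 1x1 grid.  Convergence bookkeeping is the
    same as the serial driver.
    """
    cfg.validate_for(X)
    if grid is None:
        grid = partition_matrix(X, 1, 1)
    if (grid.n, grid.m) != (X.n, X.m):
        raise ShapeError("grid does not match matrix dimensions")
    blocks = extract_blocks(X, grid)
    if init is None:
        f = init_factors(X.n, X.m, cfg, scale=resolve_init_scale(X, cfg))
    else:
        if (init.n, init.m) != (X.n, X.m):
            raise ShapeError("initial factors do not match the data matrix")
        f = init
    U_bands = _split(f.U, grid.row_bounds)
    V_bands = _split(f.V, grid.col_bounds)
    S = f.S
    trajectory = [reconstruction_error(X, f)]
    converged = False
    iterations = 0
    for it in range(1, cfg.max_iter + 1):
        U_bands, V_bands, S = blockwise_iteration(blocks, U_bands, V_bands, S, cfg)
        iterations = it
        if it % cfg.check_every == 0 or it == cfg.max_iter:
            f = FactorTriple(np.vstack(U_bands), S, np.vstack(V_bands))
            obj = reconstruction_error(X, f)
            if not np.isfinite(obj):
                raise NumericalError(f"objective became non-finite at iteration {it}")
            prev = trajectory[-1]
            trajectory.append(obj)
            if abs(obj - prev) / max(prev, cfg.epsilon) < cfg.tol:
                converged = True
                break
    f = FactorTriple(np.vstack(U_bands), S, np.vstack(V_bands))
    return FitResult(
        factors=f,
        objective_trajectory=np.asarray(trajectory),
        converged=converged,
        iterations_run=iterations,
        grid=grid,
    )
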