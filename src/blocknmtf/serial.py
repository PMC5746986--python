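"""Serial (non-partitioned) multiplicative update rules.

These are the reference rules every block-wise path must reproduce.  For
the plain (non-orthogonal) model the rules are

.. math::

    U &\\leftarrow U \\circ \\frac{X V S^T}{U S V^T V S^T}, \\\\
    V &\\leftarrow V \\circ \\frac{X^T U S}{V S^T U^T U S}, \\\\
    S &\\leftarrow S \\circ \\frac{U^T X V}{U^T U S V^T V},

with elementwise product and division.  The orthogonal variant, which
drives the factors toward ``U^T U = I`` and ``V^T V = I``, multiplies by
the square root of a guarded ratio instead:

.. math::

    U &\\leftarrow U \\circ \\sqrt{\\frac{X V S^T}{U U^T X V S^T}}, \\\\
    V &\\leftarrow V \\circ \\sqrt{\\frac{X^T U S}{V V^T X^T U S}}, \\\\
    S &\\leftarrow S \\circ \\sqrt{\\frac{U^T X V}{U^T U S V^T V}}.

Denominators are guarded below by ``eps`` (``max(den, eps)``), which keeps
the multiplicative-zero semantics: an entry that is zero stays zero, and a
vanishing denominator cannot produce inf/nan.

Association order matters for bit-level reproducibility: each rule is
evaluated through the exact grouping written in the helper functions here,
and the block-wise engine uses the same grouping so that a 1x1 grid is
bit-identical to this path.
"""

from __future__ import annotations

from typing import Optional

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

__all__ = [
    "update_u",
    "update_v",
    "update_s",
    "update_u_orth",
    "update_v_orth",
    "update_s_orth",
    "fit_serial",
]


def _check_shapes(X: DataMatrix, f: FactorTriple) -> None:
    if (X.n, X.m) != (f.n, f.m):
        raise ShapeError(
            f"data is {X.n}x{X.m} but factors reconstruct {f.n}x{f.m}"
        )


def _guard(den: np.ndarray, eps: float) -> np.ndarray:
    return np.maximum(den, eps)


# ---------------------------------------------------------------------------
# non-orthogonal rules
# ---------------------------------------------------------------------------

def update_u(X: DataMatrix, f: FactorTriple, eps: float = 1e-12) -> np.ndarray:
    """One multiplicative step on U: ``U ∘ (X V S^T) / (U S V^T V S^T)``."""
    _check_shapes(X, f)
    num = X.values @ (f.V @ f.S.T)
    den = f.U @ ((f.S @ (f.V.T @ f.V)) @ f.S.T)
    return f.U * num / _guard(den, eps)


def update_v(X: DataMatrix, f: FactorTriple, eps: float = 1e-12) -> np.ndarray:
    """One multiplicative step on V: ``V ∘ (X^T U S) / (V S^T U^T U S)``."""
    _check_shapes(X, f)
    num = (X.values.T @ f.U) @ f.S
    den = f.V @ ((f.S.T @ (f.U.T @ f.U)) @ f.S)
    return f.V * num / _guard(den, eps)


def update_s(X: DataMatrix, f: FactorTriple, eps: float = 1e-12) -> np.ndarray:
    """One multiplicative step on S: ``S ∘ (U^T X V) / (U^T U S V^T V)``."""
    _check_shapes(X, f)
    num = f.U.T @ (X.values @ f.V)
    den = ((f.U.T @ f.U) @ f.S) @ (f.V.T @ f.V)
    return f.S * num / _guard(den, eps)


# ---------------------------------------------------------------------------
# orthogonal rules
# ---------------------------------------------------------------------------

def update_u_orth(X: DataMatrix, f: FactorTriple, eps: float = 1e-12) -> np.ndarray:
    """Orthogonal U step: ``U ∘ sqrt((X V S^T) / (U U^T X V S^T))``."""
    _check_shapes(X, f)
    num = X.values @ (f.V @ f.S.T)
    den = f.U @ (f.U.T @ num)
    ratio = num / _guard(den, eps)
    assert ratio.min() >= 0.0
    return f.U * np.sqrt(ratio)


def update_v_orth(X: DataMatrix, f: FactorTriple, eps: float = 1e-12) -> np.ndarray:
    """Orthogonal V step: ``V ∘ sqrt((X^T U S) / (V V^T X^T U S))``."""
    _check_shapes(X, f)
    num = (X.values.T @ f.U) @ f.S
    den = f.V @ (f.V.T @ num)
    ratio = num / _guard(den, eps)
    assert ratio.min() >= 0.0
    return f.V * np.sqrt(ratio)


def update_s_orth(X: DataMatrix, f: FactorTriple, eps: float = 1e-12) -> np.ndarray:
    """Orthogonal S step: square-root damped version of the plain S ratio."""
    _check_shapes(X, f)
    num = f.U.T @ (X.values @ f.V)
    den = ((f.U.T @ f.U) @ f.S) @ (f.V.T @ f.V)
    ratio = num / _guard(den, eps)
    assert ratio.min() >= 0.0
    return f.S * np.sqrt(ratio)


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def _one_iteration(X: DataMatrix, f: FactorTriple, cfg: FitConfig) -> FactorTriple:
    """Update U, then V, then S, each rule seeing the freshest factors."""
    eps = cfg.epsilon
    if cfg.variant == "orthogonal":
        U = update_u_orth(X, f, eps)
        f = FactorTriple(U, f.S, f.V)
        V = update_v_orth(X, f, eps)
        f = FactorTriple(f.U, f.S, V)
        S = update_s_orth(X, f, eps)
        return FactorTriple(f.U, S, f.V)
    U = update_u(X, f, eps)
    f = FactorTriple(U, f.S, f.V)
    V = update_v(X, f, eps)
    f = FactorTriple(f.U, f.S, V)
    S = update_s(X, f, eps)
    return FactorTriple(f.U, S, f.V)


def fit_serial(
    X: DataMatrix,
    cfg: FitConfig,
    init: Optional[FactorTriple] = None,
) -> FitResult:
    """Run NMTF without any block partitioning.

    The objective is recorded before the first iteration and then at every
    ``check_every``-th iteration (and at ``max_iter``); the run stops early
    once the relative change between consecutive recorded values drops
    below ``tol``.  Convergence of multiplicative rules is a heuristic
    judged from the objective trajectory, not a guarantee of a global
    optimum.
    """
    cfg.validate_for(X)
    if init is None:
        f = init_factors(X.n, X.m, cfg, scale=resolve_init_scale(X, cfg))
    else:
        _check_shapes(X, init)
        f = init
    trajectory = [reconstruction_error(X, f)]
    converged = False
    iterations = 0
    for it in range(1, cfg.max_iter + 1):
        f = _one_iteration(X, f, cfg)
        iterations = it
        if it % cfg.check_every == 0 or it == cfg.max_iter:
            obj = reconstruction_error(X, f)
            if not np.isfinite(obj):
                raise NumericalError(f"objective became non-finite at iteration {it}")
            prev = trajectory[-1]
            trajectory.append(obj)
            if abs(obj - prev) / max(prev, cfg.epsilon) < cfg.tol:
                converged = True
                break
    return FitResult(
        factors=f,
        objective_trajectory=np.asarray(trajectory),
        converged=converged,
        iterations_run=iterations,
        grid=None,
    )
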