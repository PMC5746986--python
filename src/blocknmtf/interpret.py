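"""Turning fitted factors into co-clusters and choosing ranks.

A fitted triple ``X ≈ U S V^T`` is read as a co-clustering: row ``i``
belongs to the row cluster with the largest loading in ``U[i, :]``,
column ``j`` to the largest loading in ``V[j, :]``, and ``S[a, b]``
scores how strongly row cluster ``a`` interacts with column cluster
``b``.  Ranking the entries of ``S`` surfaces the most prominent
co-clusters first.

Rank selection holds out a random fraction of matrix entries, fits each
candidate ``(k1, k2)`` on the observed entries only — the multiplicative
rules are mask-weighted, so held-out cells contribute to neither
numerators nor denominators — and picks the candidate with the smallest
squared error on the held-out cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .model import (
    ConfigurationError,
    DataMatrix,
    FactorTriple,
    FitConfig,
    NumericalError,
    init_factors,
    resolve_init_scale,
)

__all__ = [
    "CoclusterResult",
    "assign_clusters",
    "fit_coclusters",
    "select_rank",
    "fit_masked",
]


@dataclass(frozen=True)
class CoclusterResult:
    """Cluster labels, the interaction matrix, and ranked cluster pairs."""

    row_labels: np.ndarray
    col_labels: np.ndarray
    interaction_scores: np.ndarray
    ranked_pairs: List[Tuple[int, int, float]]
    degenerate_rows: np.ndarray
    degenerate_cols: np.ndarray


def _argmax_labels(mat: np.ndarray, kind: str) -> Tuple[np.ndarray, np.ndarray]:
    labels = np.argmax(mat, axis=1)  # ties resolve to the lowest index
    dead = ~np.any(mat > 0, axis=1)
    if dead.any():
        warnings.warn(
            f"{int(dead.sum())} all-zero {kind} factor rows assigned to cluster 0",
            RuntimeWarning,
            stacklevel=3,
        )
        labels = labels.copy()
        labels[dead] = 0
    return labels, np.flatnonzero(dead)


def assign_clusters(f: FactorTriple) -> CoclusterResult:
    """Hard co-cluster assignment by per-row argmax of U and V.

    Ranked pairs are sorted by descending interaction score, ties broken
    by (row cluster, column cluster) index.  All-zero factor rows carry no
    signal; they are labelled 0 and reported in ``degenerate_*``.
    """
    row_labels, dead_rows = _argmax_labels(f.U, "row")
    col_labels, dead_cols = _argmax_labels(f.V, "column")
    pairs = [
        (a, b, float(f.S[a, b]))
        for a in range(f.k1)
        for b in range(f.k2)
    ]
    pairs.sort(key=lambda t: (-t[2], t[0], t[1]))
    return CoclusterResult(
        row_labels=row_labels,
        col_labels=col_labels,
        interaction_scores=f.S.copy(),
        ranked_pairs=pairs,
        degenerate_rows=dead_rows,
        degenerate_cols=dead_cols,
    )


def fit_coclusters(X: DataMatrix, cfg: FitConfig, restarts: int = 5):
    """Fit for co-cluster readout: restarted fits, best objective wins.

    Multiplicative updates converge to local optima, and a bad basin shows
    up directly as a higher final objective — so the standard remedy is a
    handful of random restarts scored by the (ground-truth-free)
    reconstruction error.  Restart ``r`` uses seed ``cfg.seed + r``; the
    orthogonal variant is the natural choice here because orthogonal
    non-negative columns have near-disjoint supports, making the argmax
    readout meaningful.

    Returns ``(FitResult, CoclusterResult)`` for the best restart.
    """
    from .serial import fit_serial

    if restarts < 1:
        raise ConfigurationError("restarts must be >= 1")
    best = None
    for r in range(restarts):
        res = fit_serial(X, cfg.with_(seed=cfg.seed + r))
        if best is None or res.objective_trajectory[-1] < best.objective_trajectory[-1]:
            best = res
    return best, assign_clusters(best.factors)


def fit_masked(
    X: np.ndarray,
    W: np.ndarray,
    cfg: FitConfig,
    init: Optional[FactorTriple] = None,
) -> FactorTriple:
    """Multiplicative NMTF on observed entries only.

    ``W`` is a 0/1 observation mask; the objective is
    ``|| W ∘ (X - U S V^T) ||_F^2`` and each rule replaces ``X`` by
    ``W ∘ X`` and the model term by ``W ∘ (U S V^T)``:

    * ``U ← U ∘ ((W∘X) V S^T) / ((W∘(U S V^T)) V S^T)``
    * ``V ← V ∘ ((W∘X)^T U S) / ((W∘(U S V^T))^T U S)``
    * ``S ← S ∘ (U^T (W∘X) V) / (U^T (W∘(U S V^T)) V)``

    With ``cfg.variant == "orthogonal"`` the square-root damped rules are
    masked the same way (every occurrence of ``X`` becomes ``W∘X``; the
    U/V denominators keep their projection form ``U (U^T num)``).

    Dense only: the mask destroys the Gram shortcuts the unmasked sparse
    path relies on.
    """
    if X.shape != W.shape:
        raise ConfigurationError("mask shape must match the data matrix")
    eps = cfg.epsilon
    WX = W * X
    if init is None:
        dm = DataMatrix(np.asarray(X, dtype=np.float64))
        f = init_factors(X.shape[0], X.shape[1], cfg, scale=resolve_init_scale(dm, cfg))
    else:
        f = init
    U, S, V = f.U.copy(), f.S.copy(), f.V.copy()
    orthogonal = cfg.variant == "orthogonal"
    for _ in range(cfg.max_iter):
        if orthogonal:
            num = WX @ (V @ S.T)
            U = U * np.sqrt(num / np.maximum(U @ (U.T @ num), eps))
            num = (WX.T @ U) @ S
            V = V * np.sqrt(num / np.maximum(V @ (V.T @ num), eps))
            WR = W * (U @ S @ V.T)
            num = U.T @ (WX @ V)
            S = S * np.sqrt(num / np.maximum(U.T @ (WR @ V), eps))
        else:
            WR = W * (U @ S @ V.T)
            VS = V @ S.T
            U = U * (WX @ VS) / np.maximum(WR @ VS, eps)
            WR = W * (U @ S @ V.T)
            US = U @ S
            V = V * (WX.T @ US) / np.maximum(WR.T @ US, eps)
            WR = W * (U @ S @ V.T)
            S = S * (U.T @ (WX @ V)) / np.maximum(U.T @ (WR @ V), eps)
    if not np.isfinite(S).all():
        raise NumericalError("masked fit produced non-finite factors")
    return FactorTriple(U, S, V)


def select_rank(
    X: DataMatrix,
    candidates: Sequence[Tuple[int, int]],
    holdout: float,
    cfg: FitConfig,
    restarts: int = 5,
) -> Tuple[Tuple[int, int], List[float]]:
    """Pick the rank pair with the lowest held-out reconstruction error.

    A fraction ``holdout`` of entries is masked out (seeded by
    ``cfg.seed``; the same mask is shared across candidates so the
    comparison is paired).  Each candidate is fitted ``restarts`` times
    from seeds ``cfg.seed + r`` and the restart with the lowest error on
    the *observed* entries represents the candidate — restart selection
    never looks at the held-out cells.  Returns the winning ``(k1, k2)``
    and the per-candidate held-out error curve.
    """
    if not candidates:
        raise ConfigurationError("candidate list must be non-empty")
    if not (0.0 < holdout < 1.0):
        raise ConfigurationError("holdout fraction must lie in (0, 1)")
    if restarts < 1:
        raise ConfigurationError("restarts must be >= 1")
    Xd = X.toarray()
    rng = np.random.default_rng(cfg.seed)
    held = rng.random(Xd.shape) < holdout
    W = (~held).astype(np.float64)
    errors: List[float] = []
    for k1, k2 in candidates:
        best_f, best_train = None, np.inf
        for r in range(restarts):
            sub = cfg.with_(k1=int(k1), k2=int(k2), seed=cfg.seed + r)
            f = fit_masked(Xd, W, sub)
            train = float(np.sum((W * (Xd - f.reconstruct())) ** 2))
            if train < best_train:
                best_f, best_train = f, train
        R = (Xd - best_f.reconstruct())[held]
        errors.append(float(np.sum(R * R)))
    best = int(np.argmin(errors))  # ties resolve to the first candidate
    return tuple(candidates[best]), errors
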