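"""Synthetic matrices with known ground truth.

Three generators cover the situations the factorisation code must handle:

* :func:`make_exact` — a matrix that *is* a rank-``(k1, k2)`` triple
  product, so the zero-error factorisation is known exactly;
* :func:`make_cocluster` — a planted co-cluster matrix: every entry is
  its block mean (indexed by the planted row and column labels) plus
  zero-truncated Gaussian noise, optionally sparsified;
* :func:`make_skewed_sparse` — a sparse matrix whose nonzeros concentrate
  in few rows under a power-law weight, the regime where nnz-balanced
  partitioning beats equal-size partitioning.

All generators are deterministic given their seed.  They emulate the
low-rank block structure the model assumes — not the marginal
distributions of any real omics data.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import scipy.sparse as sp
from scipy.stats import truncnorm

from .model import ConfigurationError, DataMatrix, FactorTriple

__all__ = [
    "PlantedModel",
    "make_exact",
    "make_exact_orthogonal",
    "make_cocluster",
    "make_skewed_sparse",
    "default_block_means",
]

#: Baseline and elevated block-mean levels used by the default pattern.
_MEAN_LOW = 0.6
_MEAN_HIGH = 1.4


@dataclass(frozen=True)
class PlantedModel:
    """Parameters of a planted co-cluster matrix."""

    n: int
    m: int
    k1: int
    k2: int
    #: default is 10% of the default block-mean spread (HIGH - LOW = 0.8)
    noise_sd: float = 0.08
    density: float = 1.0
    seed: int = 0
    block_means: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        if self.k1 > self.n or self.k2 > self.m:
            raise ConfigurationError("more clusters than rows/columns")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if not (0 < self.density <= 1):
            raise ConfigurationError("density must lie in (0, 1]")
        if self.block_means is not None:
            bm = np.asarray(self.block_means, dtype=np.float64)
            if bm.shape != (self.k1, self.k2):
                raise ConfigurationError("block_means must be k1 x k2")
            if bm.min() < 0:
                raise ConfigurationError("block_means must be non-negative")
            object.__setattr__(self, "block_means", bm)


def make_exact(
    n: int, m: int, k1: int, k2: int, seed: int = 0, scale: float = 1.0
) -> Tuple[DataMatrix, FactorTriple]:
    """A matrix that factorises exactly: ``X = U0 S0 V0^T`` with strictly
    positive generating factors (uniform on ``[0.1, 1) * scale``)."""
    rng = np.random.default_rng(seed)
    U0 = scale * rng.uniform(0.1, 1.0, (n, k1))
    S0 = scale * rng.uniform(0.1, 1.0, (k1, k2))
    V0 = scale * rng.uniform(0.1, 1.0, (m, k2))
    f = FactorTriple(U0, S0, V0)
    return DataMatrix(f.reconstruct()), f


def make_exact_orthogonal(
    n: int, m: int, k1: int, k2: int, seed: int = 0
) -> Tuple[DataMatrix, FactorTriple]:
    """Exactly factorizable matrix whose U and V are column-orthonormal.

    Non-negative orthogonal columns necessarily have disjoint supports, so
    U is built from a balanced row-to-cluster assignment with positive
    entries, then column-normalised (``U^T U = I``); likewise V.  This is
    the stationarity fixture for the orthogonal update rules, which leave
    a factorisation fixed only when the orthogonality constraint actually
    holds.
    """
    if k1 > n or k2 > m:
        raise ConfigurationError("ranks exceed matrix dimensions")
    rng = np.random.default_rng(seed)

    def orthonormal_nonneg(rows: int, k: int) -> np.ndarray:
        labels = np.arange(rows) % k
        rng.shuffle(labels)
        mat = np.zeros((rows, k))
        mat[np.arange(rows), labels] = rng.uniform(0.5, 1.0, rows)
        return mat / np.linalg.norm(mat, axis=0, keepdims=True)

    U0 = orthonormal_nonneg(n, k1)
    V0 = orthonormal_nonneg(m, k2)
    S0 = rng.uniform(0.5, 1.5, (k1, k2))
    f = FactorTriple(U0, S0, V0)
    return DataMatrix(f.reconstruct()), f


def default_block_means(k1: int, k2: int, rng: np.random.Generator) -> np.ndarray:
    """Identifiable k1 x k2 block means with seeded jitter.

    Each row cluster receives a distinct non-empty subset of column
    clusters at the elevated level ``_MEAN_HIGH`` (singletons first, then
    pairs, and so on), the rest sit at ``_MEAN_LOW``, and every block is
    jittered by a uniform factor on [0.95, 1.05).  The subset scheme makes
    the planted structure identifiable: every row of the mean matrix is an
    extreme ray of the rows' conic hull (and likewise for columns), which
    is the separability condition under which a non-negative factorisation
    can recover the planted labels at all.  When ``k1 > k2`` the signal
    matrix has rank at most ``k2``; without extremality, distinct row
    clusters would be conic mixtures of others and no factorisation method
    could tell them apart, so a recovery test would measure luck rather
    than correctness.

    Requires ``k1 <= 2**k2 - 1`` (and symmetrically ``k2 <= 2**k1 - 1``),
    enough distinct subsets to give every cluster its own signature.
    """
    from itertools import combinations

    if k1 > 2**k2 - 1 or k2 > 2**k1 - 1:
        raise ConfigurationError(
            f"cannot build {k1}x{k2} signature pattern: too many clusters"
        )
    subsets = []
    for size in range(1, k2 + 1):
        subsets.extend(combinations(range(k2), size))
        if len(subsets) >= k1:
            break
    pattern = np.zeros((k1, k2))
    for r, subset in enumerate(subsets[:k1]):
        pattern[r, list(subset)] = 1.0
    bm = _MEAN_LOW + (_MEAN_HIGH - _MEAN_LOW) * pattern
    return bm * rng.uniform(0.95, 1.05, (k1, k2))


def _planted_labels(count: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Random labels with every cluster guaranteed non-empty."""
    labels = rng.integers(0, k, size=count)
    labels[:k] = np.arange(k)  # pin one member per cluster ...
    rng.shuffle(labels)  # ... then mix positions
    return labels


def make_cocluster(model: PlantedModel):
    """Planted co-cluster matrix plus its ground-truth labels.

    ``X[i, j] = block_means[r_i, c_j] + noise``, where the noise is a
    Gaussian truncated at zero (sampled with :func:`scipy.stats.truncnorm`
    so non-negativity holds without clipping mass onto zero).  With
    ``density < 1`` each entry is kept independently with that
    probability and the result is returned sparse.

    Returns
    -------
    (DataMatrix, row_labels, col_labels)
    """
    rng = np.random.default_rng(model.seed)
    bm = model.block_means
    if bm is None:
        bm = default_block_means(model.k1, model.k2, rng)
    row_labels = _planted_labels(model.n, model.k1, rng)
    col_labels = _planted_labels(model.m, model.k2, rng)
    mu = bm[row_labels][:, col_labels]
    if model.noise_sd > 0:
        a = (0.0 - mu) / model.noise_sd  # lower truncation bound in sd units
        X = truncnorm.rvs(
            a, np.inf, loc=mu, scale=model.noise_sd,
            size=(model.n, model.m), random_state=rng,
        )
    else:
        X = mu.copy()
    if model.density < 1.0:
        keep = rng.random((model.n, model.m)) < model.density
        X = np.where(keep, X, 0.0)
        return DataMatrix(sp.csr_matrix(X)), row_labels, col_labels
    return DataMatrix(X), row_labels, col_labels


def make_skewed_sparse(
    n: int, m: int, nnz: int, skew: float, seed: int = 0
) -> DataMatrix:
    """Sparse matrix with power-law row occupancy.

    Row ``r`` receives nonzeros with weight ``(r + 1) ** -skew``
    (``skew = 0`` is uniform); the exact total is ``nnz``.  Values are
    uniform on ``[0.1, 1)``.  Column positions within a row are drawn
    without replacement, so the per-row count never exceeds ``m``.
    """
    if nnz > n * m:
        raise ConfigurationError(f"nnz={nnz} exceeds matrix capacity {n * m}")
    if nnz < 1:
        raise ConfigurationError("nnz must be >= 1")
    if skew < 0:
        raise ConfigurationError("skew must be >= 0")
    rng = np.random.default_rng(seed)
    weights = (np.arange(1, n + 1, dtype=np.float64)) ** (-skew)
    weights /= weights.sum()
    counts = rng.multinomial(nnz, weights)
    # Cap rows at m; redistribute the overflow in descending weight order
    # so the power-law concentration survives the cap and the total stays
    # exact and deterministic.
    overflow = int(np.sum(np.maximum(counts - m, 0)))
    counts = np.minimum(counts, m)
    if overflow > 0:
        for r in np.argsort(-weights, kind="stable"):
            take = min(m - counts[r], overflow)
            counts[r] += take
            overflow -= take
            if overflow == 0:
                break
    rows = np.repeat(np.arange(n), counts)
    cols = np.concatenate(
        [rng.choice(m, size=c, replace=False) for c in counts if c > 0]
    ) if counts.sum() else np.empty(0, dtype=int)
    vals = rng.uniform(0.1, 1.0, size=int(counts.sum()))
    mat = sp.csr_matrix((vals, (rows, cols)), shape=(n, m))
    return DataMatrix(mat)
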