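"""Locally linear embedding with an out-of-sample extension.

Standard three-step construction:

1. find each point's k nearest neighbors (Euclidean distance);
2. compute barycentric reconstruction weights w_i minimizing
   ||x_i - sum_j w_ij x_j||^2 subject to sum_j w_ij = 1, regularizing the
   local Gram matrix G by reg * trace(G) * I (needed whenever G is singular,
   in particular when k exceeds the input dimension);
3. embed into d dimensions via the eigenvectors of M = (I - W)^T (I - W)
   with the smallest eigenvalues, discarding the constant eigenvector whose
   eigenvalue is ~0 (the sum-to-one constraint forces the all-ones vector
   into M's null space).

New points are mapped by the reconstruction-weight (Saul-Roweis)
out-of-sample extension: compute barycentric weights of the new point
against its k nearest *training* points and apply those weights to the
training embedding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.linalg import eigh, solve
from scipy.spatial.distance import cdist

DEFAULT_REG = 1e-3


def _knn(queries: np.ndarray, points: np.ndarray, k: int):
    """Indices and distances of each query's k nearest points (brute force).

    Exact Euclidean search; the training sets here are small (tens of
    points), where a brute-force scan beats tree structures.
    """
    d = cdist(queries, points)
    idx = np.argpartition(d, k - 1, axis=1)[:, :k]
    row = np.arange(len(queries))[:, None]
    order = np.argsort(d[row, idx], axis=1, kind="stable")
    idx = idx[row, order]
    return idx, d[row, idx]


@dataclass(frozen=True)
class EmbeddingConfig:
    """LLE hyperparameters.

    k_neighbors : neighborhood size (must be < number of training points).
    d_target : embedding dimension; clamped to min(N_train - 1, F) with a
        warning when too large. ``None`` means min(20, N_train - 2).
    reg_eps : local-Gram regularization scale (multiplies trace(G)).
    """

    k_neighbors: int = 12
    d_target: int | None = None
    reg_eps: float = DEFAULT_REG

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")
        if self.d_target is not None and self.d_target < 1:
            raise ValueError("d_target must be >= 1")
        if self.reg_eps < 0:
            raise ValueError("reg_eps must be non-negative")


def barycenter_weights(point: np.ndarray, neighbors: np.ndarray,
                       reg: float = DEFAULT_REG) -> np.ndarray:
    """Sum-to-one weights reconstructing ``point`` from ``neighbors`` rows."""
    z = neighbors - point  # shift point to origin
    gram = z @ z.T
    trace = np.trace(gram)
    ridge = reg * trace if trace > 0 else reg
    gram.flat[:: gram.shape[0] + 1] += ridge
    w = solve(gram, np.ones(len(neighbors)), assume_a="pos")
    return w / w.sum()


class LLEModel:
    """Fitted locally linear embedding of a training set.

    Attributes
    ----------
    training_points : (N, F) array the model was fitted on.
    embedding : (N, d) array; columns have zero mean (they are orthogonal
        to the constant null-space eigenvector) and satisfy the covariance
        constraint (1/N) Y^T Y = I (unit-variance components).
    """

    def __init__(self, training_points: np.ndarray, embedding: np.ndarray,
                 config: EmbeddingConfig, eigenvalues: np.ndarray) -> None:
        self.training_points = training_points
        self.embedding = embedding
        self.config = config
        self.eigenvalues = eigenvalues

    @property
    def n_components(self) -> int:
        return self.embedding.shape[1]

    def transform(self, x_new: np.ndarray) -> np.ndarray:
        """Embed one point or a batch of points (out-of-sample extension)."""
        x = np.atleast_2d(np.asarray(x_new, dtype=float))
        if x.shape[1] != self.training_points.shape[1]:
            raise ValueError(
                f"expected {self.training_points.shape[1]} features, got {x.shape[1]}"
            )
        idx, dist = _knn(x, self.training_points, self.config.k_neighbors)
        out = np.empty((x.shape[0], self.n_components))
        for i in range(x.shape[0]):
            # a query coinciding with a training point is its own exact
            # zero-error barycentric reconstruction
            if dist[i, 0] <= 1e-12 * (1.0 + np.linalg.norm(x[i])):
                out[i] = self.embedding[idx[i, 0]]
                continue
            w = barycenter_weights(x[i], self.training_points[idx[i]],
                                   reg=self.config.reg_eps)
            out[i] = w @ self.embedding[idx[i]]
        return out[0] if np.asarray(x_new).ndim == 1 else out


def reconstruction_weight_matrix(x: np.ndarray, k_neighbors: int,
                                 reg: float = DEFAULT_REG) -> np.ndarray:
    """Dense (N, N) matrix W of barycentric weights over k-NN graphs."""
    n = x.shape[0]
    idx, _ = _knn(x, x, k_neighbors + 1)
    neighbors = idx[:, 1:]  # drop self
    w = np.zeros((n, n))
    for i in range(n):
        w[i, neighbors[i]] = barycenter_weights(x[i], x[neighbors[i]], reg=reg)
    return w


def lle_fit(x: np.ndarray, config: EmbeddingConfig) -> LLEModel:
    """Fit an LLE embedding of the rows of ``x``."""
    x = np.asarray(x, dtype=float)
    n, f = x.shape
    if config.k_neighbors >= n:
        raise ValueError(
            f"k_neighbors={config.k_neighbors} must be < N={n}"
        )
    d = config.d_target if config.d_target is not None else min(20, n - 2)
    d = max(d, 1)
    limit = min(n - 1, f)
    if d > limit:
        warnings.warn(
            f"d_target={d} clamped to {limit} (N={n}, selected features={f})",
            stacklevel=2,
        )
        d = limit
    w = reconstruction_weight_matrix(x, config.k_neighbors, reg=config.reg_eps)
    m = np.eye(n) - w
    m = m.T @ m
    eigenvalues, eigenvectors = eigh(m)
    # index 0 is the constant eigenvector (eigenvalue ~ 0); discard it.
    # Normalize so (1/N) Y^T Y = I: zero-mean, unit-variance components.
    y = eigenvectors[:, 1 : d + 1] * np.sqrt(n)
    # deterministic sign: largest-|entry| coordinate is positive
    for j in range(y.shape[1]):
        pivot = np.argmax(np.abs(y[:, j]))
        if y[pivot, j] < 0:
            y[:, j] = -y[:, j]
    cfg = EmbeddingConfig(config.k_neighbors, d, config.reg_eps)
    return LLEModel(x.copy(), y, cfg, eigenvalues[1 : d + 1])
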