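"""Anatomical network construction from probabilistic-tractography fiber counts.

Probabilistic tractography seeds S streamlines per voxel (S = 5000 by
default), so a region with n voxels emits S*n streamlines in total. The
directed edge strength from region v to region u is the fraction of those
streamlines that reach u:

    e(v, u) = m(v, u) / (S * n(v))

Seed placement is randomized, so m(v, u) and m(u, v) generally differ; the
undirected connectivity strength is their mean:

    E(v, u) = (e(v, u) + e(u, v)) / 2

yielding a symmetric R x R adjacency per subject. Entries below a threshold
tau (default 0.01) are zeroed to suppress false-positive connections, the
diagonal is removed, and the upper-triangle entries become the subject's
feature vector of length R(R-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_SAMPLES_PER_VOXEL = 5000
DEFAULT_THRESHOLD = 0.01


class FiberCountError(ValueError):
    """Invalid fiber-count data (negative, NaN, or impossible counts)."""


@dataclass(frozen=True)
class FiberCountData:
    """Directed streamline counts between regions plus per-region voxel counts.

    Attributes
    ----------
    counts : (R, R) int array, counts[v, u] = streamlines seeded in v reaching u.
    voxels : (R,) int array of voxels per region, all >= 1.
    samples_per_voxel : streamlines seeded per voxel (S).
    subject_id : optional identifier carried through to outputs.
    """

    counts: np.ndarray
    voxels: np.ndarray
    samples_per_voxel: int = DEFAULT_SAMPLES_PER_VOXEL
    subject_id: str | None = None

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        voxels = np.asarray(self.voxels)
        if counts.ndim != 2 or counts.shape[0] != counts.shape[1]:
            raise FiberCountError(f"counts must be square, got {counts.shape}")
        if voxels.shape != (counts.shape[0],):
            raise FiberCountError(
                f"voxels length {voxels.shape} does not match R={counts.shape[0]}"
            )
        if np.isnan(counts).any() or np.isnan(voxels.astype(float)).any():
            raise FiberCountError("NaN in fiber-count data")
        if (counts < 0).any():
            raise FiberCountError("negative streamline count")
        if (voxels < 1).any():
            raise FiberCountError("every region needs at least one voxel")
        cap = self.samples_per_voxel * voxels[:, None]
        off = ~np.eye(counts.shape[0], dtype=bool)
        if (counts[off] > np.broadcast_to(cap, counts.shape)[off]).any():
            raise FiberCountError(
                "count exceeds seeded streamlines S*n(v) for some region pair"
            )
        object.__setattr__(self, "counts", counts)
        object.__setattr__(self, "voxels", voxels)

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]


@dataclass(frozen=True)
class ConnectivityMatrix:
    """Symmetric, thresholded, [0, 1]-valued region x region adjacency."""

    values: np.ndarray
    threshold: float = DEFAULT_THRESHOLD
    subject_id: str | None = None

    def __post_init__(self) -> None:
        e = np.asarray(self.values, dtype=float)
        if np.isnan(e).any():
            raise FiberCountError("NaN in connectivity matrix")
        if not np.allclose(e, e.T):
            raise FiberCountError("connectivity matrix must be symmetric")
        if (np.diag(e) != 0).any():
            raise FiberCountError("diagonal must be zero")
        if (e < 0).any() or (e > 1).any():
            raise FiberCountError("entries must lie in [0, 1]")
        object.__setattr__(self, "values", e)

    @property
    def n_regions(self) -> int:
        return self.values.shape[0]


@dataclass(frozen=True)
class FeatureIndexMap:
    """Bijection between feature index f and region pair (v, u), v < u.

    Ordering is row-major over the upper triangle:
    (0,1), (0,2), ..., (0,R-1), (1,2), ...
    """

    n_regions: int
    _pairs: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        rows, cols = np.triu_indices(self.n_regions, k=1)
        object.__setattr__(self, "_pairs", np.column_stack([rows, cols]))

    @property
    def n_features(self) -> int:
        return self.n_regions * (self.n_regions - 1) // 2

    def index_to_pair(self, f: int) -> tuple[int, int]:
        v, u = self._pairs[f]
        return int(v), int(u)

    def pair_to_index(self, v: int, u: int) -> int:
        if not 0 <= v < u < self.n_regions:
            raise ValueError(f"need 0 <= v < u < {self.n_regions}, got ({v}, {u})")
        # features before row v: sum_{i<v} (R-1-i); offset within row: u-v-1
        r = self.n_regions
        return v * (2 * r - v - 1) // 2 + (u - v - 1)

    def pairs(self) -> np.ndarray:
        """(F, 2) array of region pairs in feature order."""
        return self._pairs.copy()

    def pair_names(self, region_names: list[str]) -> list[str]:
        return [f"{region_names[v]}--{region_names[u]}" for v, u in self._pairs]


def directed_edge(m: float, n: int, samples_per_voxel: int = DEFAULT_SAMPLES_PER_VOXEL) -> float:
    """Directed edge strength e(v, u) = m / (S * n)."""
    if n < 1:
        raise FiberCountError("region must contain at least one voxel")
    if m < 0 or m > samples_per_voxel * n:
        raise FiberCountError(
            f"count {m} outside [0, S*n = {samples_per_voxel * n}]"
        )
    return m / (samples_per_voxel * n)


def symmetrize(e_vu: float, e_uv: float) -> float:
    """Undirected connectivity strength: the mean of the two directed edges."""
    for e in (e_vu, e_uv):
        if not 0.0 <= e <= 1.0:
            raise ValueError(f"edge strength {e} outside [0, 1]")
    return (e_vu + e_uv) / 2.0


def build_connectivity(
    data: FiberCountData, threshold: float = DEFAULT_THRESHOLD
) -> ConnectivityMatrix:
    """Normalize, symmetrize and threshold a subject's fiber counts.

    E[v, u] = (m[v,u]/(S*n[v]) + m[u,v]/(S*n[u])) / 2; entries strictly
    below ``threshold`` are zeroed (entries equal to it survive); the
    diagonal is forced to zero.
    """
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    denom = data.samples_per_voxel * data.voxels.astype(float)
    e_directed = data.counts / denom[:, None]
    e = (e_directed + e_directed.T) / 2.0
    e[e < threshold] = 0.0
    np.fill_diagonal(e, 0.0)
    return ConnectivityMatrix(np.clip(e, 0.0, 1.0), threshold=threshold,
                              subject_id=data.subject_id)


def vectorize(matrix: ConnectivityMatrix | np.ndarray,
              index_map: FeatureIndexMap) -> np.ndarray:
    """Upper-triangle feature vector of a symmetric adjacency."""
    values = matrix.values if isinstance(matrix, ConnectivityMatrix) else np.asarray(matrix)
    if values.shape != (index_map.n_regions, index_map.n_regions):
        raise ValueError(
            f"matrix shape {values.shape} does not match R={index_map.n_regions}"
        )
    rows, cols = np.triu_indices(index_map.n_regions, k=1)
    return values[rows, cols]


def devectorize(features: np.ndarray, index_map: FeatureIndexMap) -> np.ndarray:
    """Rebuild the symmetric adjacency from an upper-triangle feature vector."""
    features = np.asarray(features, dtype=float)
    if features.shape != (index_map.n_features,):
        raise ValueError(
            f"expected {index_map.n_features} features, got {features.shape}"
        )
    r = index_map.n_regions
    out = np.zeros((r, r))
    rows, cols = np.triu_indices(r, k=1)
    out[rows, cols] = features
    out[cols, rows] = features
    return out
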