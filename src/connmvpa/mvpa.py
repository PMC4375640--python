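"""Discriminative machinery: t-test feature selection, SVM contract,
consensus features across cross-validation folds, and region weights.

Feature selection is a mass-univariate two-sample t-test: a feature
(connection) is kept when its two-sided p-value falls below alpha. Because
selection is recomputed inside every training fold, the selected sets vary
slightly across folds; the intersection over all folds — the *consensus
features* — are the connections reported as discriminative, and each
region's *weight* is the summed |t| of consensus connections incident on
it, normalized so the maximum weight is 1.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats
from sklearn.svm import SVC

from .network import FeatureIndexMap

logger = logging.getLogger(__name__)


@dataclass
class LabeledDataset:
    """Subjects x upper-triangle-feature matrix with group labels.

    x : (N, F) feature matrix, F = R(R-1)/2 for the dataset's parcellation.
    y : length-N group labels (2 or 3 distinct values, each with >= 2
        subjects so a t-test has within-group variance).
    index_map : feature-index <-> region-pair bijection.
    subject_ids : optional per-subject identifiers.
    """

    x: np.ndarray
    y: np.ndarray
    index_map: FeatureIndexMap
    subject_ids: list | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y)
        if self.x.ndim != 2 or self.x.shape[0] != len(self.y):
            raise ValueError("x must be (N, F) with one label per row")
        if self.x.shape[1] != self.index_map.n_features:
            raise ValueError(
                f"F={self.x.shape[1]} does not match index map "
                f"({self.index_map.n_features} features)"
            )
        labels, counts = np.unique(self.y, return_counts=True)
        if (counts < 2).any():
            small = labels[counts < 2]
            raise ValueError(f"group(s) with < 2 subjects: {list(small)}")
        if self.subject_ids is not None and len(self.subject_ids) != len(self.y):
            raise ValueError("subject_ids length mismatch")

    @property
    def n_subjects(self) -> int:
        return self.x.shape[0]

    @property
    def groups(self) -> list:
        return list(np.unique(self.y))

    def subset(self, groups) -> "LabeledDataset":
        """Restrict to subjects whose label is in ``groups``."""
        missing = [g for g in groups if g not in self.y]
        if missing:
            raise ValueError(
                f"group(s) {missing} not in dataset; available: {self.groups}"
            )
        keep = np.isin(self.y, list(groups))
        ids = ([s for s, k in zip(self.subject_ids, keep) if k]
               if self.subject_ids is not None else None)
        return LabeledDataset(self.x[keep], self.y[keep], self.index_map, ids)


@dataclass(frozen=True)
class SelectionRule:
    """Two-sample t-test filter.

    alpha : two-sided significance level for keeping a feature.
    variant : "pooled" (Student's, default) or "welch".
    fallback_k : when no feature passes alpha, keep the fallback_k
        smallest-p features instead (with a warning) so cross-validation
        never aborts mid-run.
    """

    alpha: float = 0.05
    variant: str = "pooled"
    fallback_k: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.variant not in ("pooled", "welch"):
            raise ValueError("variant must be 'pooled' or 'welch'")
        if self.fallback_k < 1:
            raise ValueError("fallback_k must be >= 1")


def ttest_select(
    x_train: np.ndarray, y_train: np.ndarray, rule: SelectionRule
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Select features significantly different between the two groups.

    Returns (selected feature ids, t values, p values). Features with zero
    variance in both groups and equal means get t = 0, p = 1; zero variance
    with unequal means is maximally significant (p = 0).
    """
    x_train = np.asarray(x_train, dtype=float)
    y_train = np.asarray(y_train)
    classes = np.unique(y_train)
    if classes.size != 2:
        raise ValueError(f"ttest_select needs exactly 2 classes, got {classes.size}")
    a = x_train[y_train == classes[0]]
    b = x_train[y_train == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each class needs >= 2 subjects for a t-test")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        t, p = stats.ttest_ind(a, b, axis=0, equal_var=(rule.variant == "pooled"))
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        diff = a.mean(axis=0) - b.mean(axis=0)
        same = degenerate & (diff == 0)
        t[same], p[same] = 0.0, 1.0
        split = degenerate & (diff != 0)
        t[split] = np.sign(diff[split]) * np.inf
        p[split] = 0.0
    selected = np.flatnonzero(p < rule.alpha)
    if selected.size == 0:
        k = min(rule.fallback_k, x_train.shape[1])
        selected = np.sort(np.argsort(p, kind="stable")[:k])
        logger.warning(
            "no feature passed alpha=%.3g; falling back to the %d smallest-p features",
            rule.alpha, k,
        )
    return selected, t, p


@dataclass(frozen=True)
class SVMParams:
    """RBF-kernel SVM defaults: C = 1, gamma = 1/d (set at train time)."""

    C: float = 1.0
    gamma: float | None = None  # None -> 1 / embedding dimension


def train_classifier(z_train: np.ndarray, y_train: np.ndarray,
                     params: SVMParams = SVMParams()) -> SVC:
    """Train the Gaussian-RBF SVM on embedded training points."""
    z_train = np.asarray(z_train, dtype=float)
    if np.unique(y_train).size < 2:
        raise ValueError("training labels contain a single class")
    gamma = params.gamma if params.gamma is not None else 1.0 / z_train.shape[1]
    clf = SVC(kernel="rbf", C=params.C, gamma=gamma)
    clf.fit(z_train, y_train)
    return clf


@dataclass(frozen=True)
class ConsensusResult:
    """Connections selected in every cross-validation fold.

    feature_ids : sorted ids of the consensus features.
    mean_t : per-consensus-feature t statistic averaged over folds.
    direction : sign of (class-A mean - class-B mean) on the full dataset
        (+1: higher in class A; -1: lower). Reporting only — not part of
        the nested classifier.
    classes : the (A, B) label pair the directions refer to.
    """

    feature_ids: np.ndarray
    mean_t: np.ndarray
    direction: np.ndarray
    classes: tuple = field(default=(None, None))

    @property
    def n_features(self) -> int:
        return self.feature_ids.size


def consensus_features(
    fold_selections: list[np.ndarray],
    fold_t_values: list[np.ndarray] | None = None,
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    classes: tuple | None = None,
) -> ConsensusResult:
    """Intersect per-fold selections and attach fold-averaged statistics.

    ``fold_t_values`` holds each fold's full-length t vector (may be None,
    leaving mean_t at NaN). ``x``/``y`` supply the full dataset for the
    direction of the group difference; ``classes`` fixes which label is
    class A (default: sorted label order).
    """
    if not fold_selections:
        raise ValueError("need at least one fold")
    consensus = set(np.asarray(fold_selections[0]).tolist())
    for sel in fold_selections[1:]:
        consensus &= set(np.asarray(sel).tolist())
    ids = np.array(sorted(consensus), dtype=int)
    mean_t = np.full(ids.size, np.nan)
    if fold_t_values is not None and ids.size:
        mean_t = np.mean([tv[ids] for tv in fold_t_values], axis=0)
    direction = np.zeros(ids.size, dtype=int)
    pair = (None, None)
    if x is not None and y is not None and ids.size:
        y = np.asarray(y)
        cls = tuple(classes) if classes is not None else tuple(np.unique(y))
        if len(cls) != 2 or any(c not in y for c in cls):
            raise ValueError(f"classes {cls} must be two labels present in y")
        pair = cls
        diff = (np.asarray(x)[y == cls[0]][:, ids].mean(axis=0)
                - np.asarray(x)[y == cls[1]][:, ids].mean(axis=0))
        direction = np.where(diff >= 0, 1, -1)
    return ConsensusResult(ids, mean_t, direction, pair)


def region_weights(consensus: ConsensusResult, index_map: FeatureIndexMap,
                   n_regions: int | None = None) -> np.ndarray:
    """Per-region discriminative load of the consensus connections.

    weight(r) = sum over consensus features incident on region r of
    |mean t|, then normalized so the maximum weight is 1. Regions touching
    no consensus feature get 0. Infinite t values (degenerate zero-variance
    splits) are capped to the largest finite |t| to keep weights finite.
    """
    r = n_regions if n_regions is not None else index_map.n_regions
    weights = np.zeros(r)
    if consensus.n_features == 0:
        return weights
    abs_t = np.abs(consensus.mean_t)
    if np.isinf(abs_t).any():
        finite = abs_t[np.isfinite(abs_t)]
        cap = finite.max() if finite.size else 1.0
        abs_t = np.where(np.isinf(abs_t), cap, abs_t)
    abs_t = np.where(np.isnan(abs_t), 1.0, abs_t)
    for fid, w in zip(consensus.feature_ids, abs_t):
        v, u = index_map.index_to_pair(int(fid))
        weights[v] += w
        weights[u] += w
    top = weights.max()
    if top > 0:
        weights /= top
    return weights
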