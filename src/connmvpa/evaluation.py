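"""Cross-validation, performance metrics, permutation significance and ROC.

The classification pipeline (t-test selection -> locally linear embedding
-> RBF-SVM) is *nested*: every stage is fitted on the training subjects of
a fold only, and held-out subjects are mapped into the fold's embedding by
the out-of-sample extension before prediction. Leave-one-out
cross-validation (LOOCV) is the primary scheme; k-fold (default
stratified) is available as an alternative.

Performance is summarized as the generalization rate GR (overall fraction
correct), sensitivity SS (fraction of the positive/patient class correct)
and specificity SC (fraction of the other class correct). Significance of
an observed GR is assessed by permutation: labels are randomly reassigned,
the *entire* nested cross-validation is rerun, and the p-value is the
fraction of permutations whose GR is strictly higher than the observed one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import KFold, LeaveOneOut, StratifiedKFold

from .lle import EmbeddingConfig, lle_fit
from .mvpa import SelectionRule, SVMParams, train_classifier, ttest_select


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation scheme: LOOCV (default) or (stratified) k-fold."""

    kind: str = "loocv"
    k: int = 10
    stratified: bool = True
    shuffle_seed: int | None = 0

    def __post_init__(self) -> None:
        if self.kind not in ("loocv", "kfold"):
            raise ValueError("kind must be 'loocv' or 'kfold'")
        if self.kind == "kfold" and self.k < 2:
            raise ValueError("k-fold needs k >= 2")

    def splits(self, y: np.ndarray):
        n = len(y)
        if self.kind == "loocv":
            return LeaveOneOut().split(np.zeros(n))
        if self.k > n:
            raise ValueError(f"k={self.k} exceeds N={n}")
        if self.stratified:
            cv = StratifiedKFold(self.k, shuffle=True, random_state=self.shuffle_seed)
            return cv.split(np.zeros(n), y)
        cv = KFold(self.k, shuffle=True, random_state=self.shuffle_seed)
        return cv.split(np.zeros(n))


@dataclass(frozen=True)
class PipelineConfig:
    """Bundle of the per-fold pipeline stages' settings."""

    selection: SelectionRule = SelectionRule()
    embedding: EmbeddingConfig | None = None  # None -> auto per fold size
    svm: SVMParams = SVMParams()


def _resolve_embedding(config: EmbeddingConfig | None, n_train: int,
                       n_selected: int) -> EmbeddingConfig:
    """Fill in fold-size-dependent defaults and clamp d to valid range."""
    if config is None:
        k = min(12, n_train - 2)
        d = min(20, n_train - 2)
        reg = 1e-3
    else:
        k, d, reg = config.k_neighbors, config.d_target, config.reg_eps
        if d is None:
            d = min(20, n_train - 2)
        if k >= n_train:
            raise ValueError(f"k_neighbors={k} must be < training size {n_train}")
    k = max(1, k)
    d = max(1, min(d, n_train - 1, n_selected))
    return EmbeddingConfig(k, d, reg)


def _fit_fold(x_train: np.ndarray, y_train: np.ndarray,
              pipeline: PipelineConfig):
    """Fit selection + embedding + classifier on one training fold."""
    selected, t_vals, _ = ttest_select(x_train, y_train, pipeline.selection)
    cfg = _resolve_embedding(pipeline.embedding, len(x_train), selected.size)
    model = lle_fit(x_train[:, selected], cfg)
    clf = train_classifier(model.embedding, y_train, pipeline.svm)
    return selected, t_vals, model, clf


@dataclass
class CVResult:
    """Aggregated nested cross-validation outcome."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray  # signed decision values, positive = positive_class
    positive_class: object
    negative_class: object
    gr: float
    ss: float
    sc: float
    confusion: dict
    n_folds: int
    fold_selections: list = field(default_factory=list)
    fold_t_values: list = field(default_factory=list)

    def as_dict(self) -> dict:
        return {
            "gr": self.gr, "ss": self.ss, "sc": self.sc,
            "positive_class": str(self.positive_class),
            "negative_class": str(self.negative_class),
            "n_folds": self.n_folds,
            "confusion": self.confusion,
            "y_true": [str(v) for v in self.y_true],
            "y_pred": [str(v) for v in self.y_pred],
            "scores": [float(s) for s in self.scores],
        }


def metrics(predictions: np.ndarray, truth: np.ndarray,
            positive_class) -> tuple[float, float, float]:
    """(GR, SS, SC) as fractions in [0, 1].

    GR is the overall fraction correct, SS the fraction of the positive
    class predicted correctly, SC the fraction of the remaining class.
    """
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.size == 0 or predictions.shape != truth.shape:
        raise ValueError("predictions and truth must be equal-length and non-empty")
    if positive_class not in truth:
        raise ValueError(f"positive class {positive_class!r} absent from truth")
    correct = predictions == truth
    pos = truth == positive_class
    gr = correct.mean()
    ss = correct[pos].mean()
    sc = correct[~pos].mean() if (~pos).any() else float("nan")
    return float(gr), float(ss), float(sc)


def run_cv(
    x: np.ndarray,
    y: np.ndarray,
    pipeline: PipelineConfig = PipelineConfig(),
    scheme: CVScheme = CVScheme(),
    feature_mask: np.ndarray | None = None,
    positive_class=None,
    record: bool = True,
) -> CVResult:
    """Nested cross-validation of the two-group pipeline.

    Per fold: apply the optional feature keep-mask, select features on the
    training subjects only, fit the embedding and SVM on the training
    subjects only, then out-of-sample-embed and classify the held-out
    subjects. ``record=True`` keeps each fold's selected feature ids (as
    indices into the *unmasked* feature space) and t vectors for the
    consensus analysis.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError(f"run_cv needs exactly 2 classes, got {classes.size}")
    if positive_class is None:
        positive_class = classes[0]
    if positive_class not in classes:
        raise ValueError(f"positive class {positive_class!r} not in labels")
    negative_class = classes[classes != positive_class][0]

    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        if feature_mask.shape != (x.shape[1],):
            raise ValueError("feature mask length must equal feature count")
        keep = np.flatnonzero(feature_mask)
        x_masked = x[:, keep]
    else:
        keep = np.arange(x.shape[1])
        x_masked = x

    y_pred = np.empty(len(y), dtype=y.dtype)
    scores = np.empty(len(y))
    fold_selections: list[np.ndarray] = []
    fold_t_values: list[np.ndarray] = []
    n_folds = 0
    for train_idx, test_idx in scheme.splits(y):
        if np.unique(y[train_idx]).size < 2:
            raise ValueError(
                f"fold {n_folds} has a single training class; "
                "use fewer folds or stratification"
            )
        selected, t_vals, model, clf = _fit_fold(
            x_masked[train_idx], y[train_idx], pipeline
        )
        z_test = model.transform(x_masked[np.ix_(test_idx, selected)])
        pred = clf.predict(np.atleast_2d(z_test))
        dec = np.ravel(clf.decision_function(np.atleast_2d(z_test)))
        if clf.classes_[1] != positive_class:  # SVC scores favor classes_[1]
            dec = -dec
        y_pred[test_idx] = pred
        scores[test_idx] = dec
        if record:
            fold_selections.append(keep[selected])
            t_full = np.full(x.shape[1], np.nan)
            t_full[keep] = t_vals
            fold_t_values.append(t_full)
        n_folds += 1

    gr, ss, sc = metrics(y_pred, y, positive_class)
    pos = y == positive_class
    confusion = {
        "tp": int((y_pred[pos] == positive_class).sum()),
        "fn": int((y_pred[pos] != positive_class).sum()),
        "tn": int((y_pred[~pos] == negative_class).sum()),
        "fp": int((y_pred[~pos] != negative_class).sum()),
    }
    return CVResult(y.copy(), y_pred, scores, positive_class, negative_class,
                    gr, ss, sc, confusion, n_folds,
                    fold_selections, fold_t_values)


@dataclass
class PermutationResult:
    """Null distribution of GR under label permutation."""

    observed_gr: float
    null_gr: np.ndarray
    n_perm: int
    p_value: float
    seed: int
    add_one: bool = False

    def as_dict(self) -> dict:
        return {
            "observed_gr": self.observed_gr,
            "n_perm": self.n_perm,
            "p_value": self.p_value,
            "p_rule": "(count+1)/(n+1)" if self.add_one else "count/n",
            "seed": self.seed,
            "null_gr": [float(g) for g in self.null_gr],
        }


def _one_permutation(x, y, pipeline, scheme, feature_mask, seed, index):
    rng = np.random.default_rng([seed, index])
    y_perm = rng.permutation(y)
    res = run_cv(x, y_perm, pipeline, scheme, feature_mask, record=False)
    return res.gr


def permutation_test(
    x: np.ndarray,
    y: np.ndarray,
    pipeline: PipelineConfig = PipelineConfig(),
    scheme: CVScheme = CVScheme(),
    feature_mask: np.ndarray | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    n_jobs: int = 1,
    observed_gr: float | None = None,
    add_one: bool = False,
) -> PermutationResult:
    """Permutation significance of the cross-validated accuracy.

    Each permutation reassigns labels uniformly at random over subjects
    (class counts preserved) and reruns the entire nested cross-validation.
    p = (# null GR strictly greater than observed) / n_perm; ties count as
    not-higher. ``add_one`` switches to the (count+1)/(n_perm+1) estimator.
    Per-permutation RNG streams are derived from (seed, index), so serial
    and parallel runs agree exactly.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if observed_gr is None:
        observed_gr = run_cv(x, y, pipeline, scheme, feature_mask,
                             record=False).gr
    null = Parallel(n_jobs=n_jobs)(
        delayed(_one_permutation)(x, y, pipeline, scheme, feature_mask, seed, i)
        for i in range(n_perm)
    )
    null = np.asarray(null)
    count = int((null > observed_gr).sum())
    p = (count + 1) / (n_perm + 1) if add_one else count / n_perm
    return PermutationResult(float(observed_gr), null, n_perm, float(p),
                             seed, add_one)


def roc_points(scores: np.ndarray, truth: np.ndarray,
               positive_class) -> tuple[np.ndarray, np.ndarray, float]:
    """ROC sweep over decision-score thresholds: (FPR, TPR, AUC)."""
    truth = np.asarray(truth)
    scores = np.asarray(scores, dtype=float)
    if np.unique(truth).size < 2:
        raise ValueError("ROC needs both classes present")
    if not np.isfinite(scores).all():
        raise ValueError("decision scores must be finite")
    fpr, tpr, _ = _roc_curve(truth, scores, pos_label=positive_class)
    return fpr, tpr, float(_auc(fpr, tpr))


@dataclass
class ThreeWayResult:
    """One-against-one multi-class cross-validation outcome."""

    y_true: np.ndarray
    y_pred: np.ndarray
    classes: np.ndarray
    per_class_accuracy: dict
    total_accuracy: float
    n_folds: int

    def as_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "per_class_accuracy": {str(k): v for k, v in
                                   self.per_class_accuracy.items()},
            "total_accuracy": self.total_accuracy,
            "n_folds": self.n_folds,
            "y_true": [str(v) for v in self.y_true],
            "y_pred": [str(v) for v in self.y_pred],
        }


def vote(pair_predictions: list, pair_scores: list, classes: np.ndarray):
    """Majority vote over one-against-one predictions for one subject.

    Ties are broken by the largest summed absolute decision score among the
    tied classes, then by the lowest class index.
    """
    votes = {c: 0 for c in classes}
    score_sum = {c: 0.0 for c in classes}
    for pred, score in zip(pair_predictions, pair_scores):
        votes[pred] += 1
        score_sum[pred] += abs(score)
    order = {c: i for i, c in enumerate(classes)}
    best = max(classes, key=lambda c: (votes[c], score_sum[c], -order[c]))
    return best


def three_way_cv(
    x: np.ndarray,
    y: np.ndarray,
    pipeline: PipelineConfig = PipelineConfig(),
    scheme: CVScheme = CVScheme(),
    feature_mask: np.ndarray | None = None,
) -> ThreeWayResult:
    """One-against-one three-class nested cross-validation.

    Per fold, each of the three pairwise classifiers runs its own nested
    selection + embedding on the training subjects of its class pair; the
    held-out subjects are labeled by majority vote.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size != 3:
        raise ValueError(f"three_way_cv needs exactly 3 classes, got {classes.size}")

    if feature_mask is not None:
        feature_mask = np.asarray(feature_mask, dtype=bool)
        x = x[:, feature_mask]

    pairs = [(classes[i], classes[j]) for i in range(3) for j in range(i + 1, 3)]
    y_pred = np.empty(len(y), dtype=y.dtype)
    n_folds = 0
    for train_idx, test_idx in scheme.splits(y):
        fold_preds: list[list] = [[] for _ in test_idx]
        fold_scores: list[list] = [[] for _ in test_idx]
        for a, b in pairs:
            sub = train_idx[np.isin(y[train_idx], (a, b))]
            if np.unique(y[sub]).size < 2:
                raise ValueError(
                    f"fold {n_folds}: pair ({a!r}, {b!r}) lost a class in training"
                )
            selected, _, model, clf = _fit_fold(x[sub], y[sub], pipeline)
            z = np.atleast_2d(model.transform(x[np.ix_(test_idx, selected)]))
            pred = clf.predict(z)
            dec = np.ravel(clf.decision_function(z))
            for t in range(len(test_idx)):
                fold_preds[t].append(pred[t])
                fold_scores[t].append(dec[t])
        for t, subject in enumerate(test_idx):
            y_pred[subject] = vote(fold_preds[t], fold_scores[t], classes)
        n_folds += 1

    per_class = {
        c: float((y_pred[y == c] == c).mean()) for c in classes
    }
    total = float((y_pred == y).mean())
    return ThreeWayResult(y.copy(), y_pred, classes, per_class, total, n_folds)
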