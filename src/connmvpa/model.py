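"""Model/Results interface over the connectome-classification pipeline.

``ConnectomeMVPA`` is constructed from a labeled feature dataset (built
from per-subject connectivity matrices); ``fit`` runs the nested
cross-validated pipeline for one group pair and returns an ``MVPAResults``
carrying accuracies, consensus features, region weights and diagnostics,
with ``summary()``, ``permutation_test()`` and ``roc()`` hanging off it.

Example
-------
>>> from connmvpa import ConnectomeMVPA, SyntheticSpec, generate_dataset
>>> study = generate_dataset(SyntheticSpec(seed=7))
>>> model = ConnectomeMVPA(study.dataset)
>>> res = model.fit(groups=("left_mtle", "control"))
>>> print(res.summary())            # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from . import atlas as _atlas
from .evaluation import (
    CVResult,
    CVScheme,
    PermutationResult,
    PipelineConfig,
    ThreeWayResult,
    permutation_test,
    roc_points,
    run_cv,
    three_way_cv,
)
from .lle import EmbeddingConfig
from .mvpa import (
    ConsensusResult,
    LabeledDataset,
    SelectionRule,
    SVMParams,
    consensus_features,
    region_weights,
)


def _pct(x: float) -> str:
    return f"{100 * x:.1f}%"


class ConnectomeMVPA:
    """Multivariate pattern analysis of anatomical connectivity networks.

    Parameters
    ----------
    dataset : LabeledDataset of upper-triangle connectivity features.
    region_table : parcellation metadata; defaults to the shipped AAL-116
        table when the dataset has 116 regions (needed only for lobe masks
        and region names in reports).
    selection, embedding, svm : pipeline stage settings. ``embedding=None``
        sizes the LLE neighborhood/dimension from each training fold
        (k = min(12, N_train - 2), d = min(20, N_train - 2)).
    """

    def __init__(
        self,
        dataset: LabeledDataset,
        region_table: _atlas.RegionTable | None = None,
        selection: SelectionRule = SelectionRule(),
        embedding: EmbeddingConfig | None = None,
        svm: SVMParams = SVMParams(),
    ) -> None:
        self.dataset = dataset
        if region_table is None and dataset.index_map.n_regions == 116:
            region_table = _atlas.load_region_table()
        self.region_table = region_table
        self.pipeline = PipelineConfig(selection, embedding, svm)

    @classmethod
    def from_manifest(cls, manifest_path, region_table=None,
                      threshold: float = 0.01, samples_per_voxel: int = 5000,
                      **kwargs) -> "ConnectomeMVPA":
        """Build the model from a manifest of per-subject count files."""
        from .io import load_manifest_dataset

        dataset = load_manifest_dataset(manifest_path, threshold=threshold,
                                        samples_per_voxel=samples_per_voxel)
        return cls(dataset, region_table=region_table, **kwargs)

    # -- masking -----------------------------------------------------------
    def lobe_feature_mask(self, lobes) -> np.ndarray:
        """Keep-mask excluding every feature incident on the given lobes."""
        if self.region_table is None:
            raise ValueError("a region table is required for lobe masking")
        masked = _atlas.regions_in_lobes(self.region_table, set(lobes))
        return _atlas.feature_mask(masked, self.dataset.index_map.n_regions)

    def _build_mask(self, mask_lobes, feature_mask):
        if mask_lobes is not None and feature_mask is not None:
            raise ValueError("pass mask_lobes or feature_mask, not both")
        if mask_lobes is not None:
            return self.lobe_feature_mask(mask_lobes)
        return feature_mask

    # -- fitting -----------------------------------------------------------
    def fit(self, groups=None, scheme: CVScheme = CVScheme(),
            mask_lobes=None, feature_mask=None,
            positive_class=None) -> "MVPAResults":
        """Nested cross-validation of one two-group comparison.

        ``groups`` picks the pair of labels (defaults to the dataset's two
        groups; required when the dataset has three). The first group of
        the pair is the positive class unless ``positive_class`` is given.
        """
        if groups is None:
            if len(self.dataset.groups) != 2:
                raise ValueError(
                    f"dataset has groups {self.dataset.groups}; pass groups=(a, b)"
                )
            groups = tuple(self.dataset.groups)
        if len(groups) != 2:
            raise ValueError("groups must name exactly two labels")
        data = self.dataset.subset(groups)
        mask = self._build_mask(mask_lobes, feature_mask)
        if positive_class is None:
            positive_class = groups[0]
        cv = run_cv(data.x, data.y, self.pipeline, scheme,
                    feature_mask=mask, positive_class=positive_class)
        consensus = consensus_features(cv.fold_selections, cv.fold_t_values,
                                       data.x, data.y, classes=groups)
        weights = region_weights(consensus, data.index_map)
        return MVPAResults(self, data, groups, scheme, mask, cv,
                           consensus, weights)

    def fit_threeway(self, scheme: CVScheme = CVScheme(),
                     mask_lobes=None, feature_mask=None) -> "ThreeWayResults":
        """One-against-one three-class nested cross-validation."""
        if len(self.dataset.groups) != 3:
            raise ValueError(
                f"three-way fit needs 3 groups, dataset has {self.dataset.groups}"
            )
        mask = self._build_mask(mask_lobes, feature_mask)
        res = three_way_cv(self.dataset.x, self.dataset.y, self.pipeline,
                           scheme, feature_mask=mask)
        return ThreeWayResults(self, scheme, mask, res)


class MVPAResults:
    """Fitted two-group comparison: accuracies, consensus, diagnostics."""

    def __init__(self, model: ConnectomeMVPA, data: LabeledDataset, groups,
                 scheme: CVScheme, mask, cv: CVResult,
                 consensus: ConsensusResult, weights: np.ndarray) -> None:
        self.model = model
        self.data = data
        self.groups = tuple(groups)
        self.scheme = scheme
        self.feature_mask = mask
        self.cv = cv
        self.consensus_ = consensus
        self.region_weights_ = weights

    # convenient scalar views
    gr = property(lambda self: self.cv.gr)
    ss = property(lambda self: self.cv.ss)
    sc = property(lambda self: self.cv.sc)

    @property
    def n_features_used(self) -> int:
        if self.feature_mask is None:
            return self.data.index_map.n_features
        return int(np.count_nonzero(self.feature_mask))

    def permutation_test(self, n_perm: int = 10_000, seed: int = 0,
                         n_jobs: int = 1, add_one: bool = False) -> PermutationResult:
        """Permutation significance of this comparison's GR (same pipeline)."""
        return permutation_test(
            self.data.x, self.data.y, self.model.pipeline,
            replace(self.scheme), feature_mask=self.feature_mask,
            n_perm=n_perm, seed=seed, n_jobs=n_jobs,
            observed_gr=self.cv.gr, add_one=add_one,
        )

    def roc(self):
        """(FPR, TPR, AUC) from the pooled held-out decision scores."""
        return roc_points(self.cv.scores, self.cv.y_true, self.cv.positive_class)

    def top_regions(self, n: int = 10) -> list:
        """Regions with the largest consensus weights, as (name, weight)."""
        order = np.argsort(self.region_weights_)[::-1][:n]
        names = (self.model.region_table.names
                 if self.model.region_table is not None
                 else [f"region_{i}" for i in range(len(self.region_weights_))])
        return [(names[i], float(self.region_weights_[i]))
                for i in order if self.region_weights_[i] > 0]

    def summary(self) -> str:
        counts = np.unique(self.data.y, return_counts=True)
        sizes = dict(zip(*counts))
        _, _, auc = self.roc()
        lines = [
            "Connectome MVPA Results",
            "=" * 54,
            f"Comparison:        {self.groups[0]} vs {self.groups[1]}",
            f"Subjects:          "
            + " + ".join(f"{sizes[g]} {g}" for g in self.groups)
            + f" = {self.data.n_subjects}",
            f"Features used:     {self.n_features_used} of "
            f"{self.data.index_map.n_features}",
            f"CV scheme:         {self.scheme.kind} ({self.cv.n_folds} folds)",
            "-" * 54,
            f"GR (accuracy):     {_pct(self.gr)}",
            f"SS (sensitivity):  {_pct(self.ss)}   [positive: {self.cv.positive_class}]",
            f"SC (specificity):  {_pct(self.sc)}",
            f"ROC AUC:           {auc:.3f}",
            f"Consensus features (selected in every fold): "
            f"{self.consensus_.n_features}",
        ]
        top = self.top_regions(5)
        if top:
            lines.append("Top regions by weight: "
                         + ", ".join(f"{n} ({w:.2f})" for n, w in top))
        lines.append("=" * 54)
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return {
            "groups": [str(g) for g in self.groups],
            "n_features_used": self.n_features_used,
            "cv": self.cv.as_dict(),
            "consensus": {
                "feature_ids": [int(i) for i in self.consensus_.feature_ids],
                "mean_t": [float(t) for t in self.consensus_.mean_t],
                "direction": [int(d) for d in self.consensus_.direction],
            },
            "region_weights": [float(w) for w in self.region_weights_],
        }


class ThreeWayResults:
    """Fitted one-against-one three-class comparison."""

    def __init__(self, model: ConnectomeMVPA, scheme: CVScheme, mask,
                 res: ThreeWayResult) -> None:
        self.model = model
        self.scheme = scheme
        self.feature_mask = mask
        self.result = res

    total_accuracy = property(lambda self: self.result.total_accuracy)
    per_class_accuracy = property(lambda self: self.result.per_class_accuracy)

    def summary(self) -> str:
        lines = [
            "Connectome MVPA Results (three-way, one-against-one)",
            "=" * 54,
            f"CV scheme:         {self.scheme.kind} ({self.result.n_folds} folds)",
        ]
        for c in self.result.classes:
            lines.append(f"  {c}: {_pct(self.per_class_accuracy[c])}")
        lines.append(f"Total accuracy:    {_pct(self.total_accuracy)}")
        lines.append("=" * 54)
        return "\n".join(lines)

    def as_dict(self) -> dict:
        return self.result.as_dict()
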