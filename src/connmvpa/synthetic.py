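"""Synthetic fiber-count datasets with planted group differences.

The generator emulates the statistical structure the analysis assumes —
not brain anatomy. A sparse symmetric baseline adjacency (nonzero edge
strengths uniform on [edge_low, edge_high]) is shared by all groups; a
small set of planted connections is shifted between groups by a configured
effect size delta (in units of the subject-level noise SD); each subject's
adjacency is the group mean plus symmetric Gaussian noise (clipped to
[0, 1], structural zeros stay zero) and is then inverted through the edge
formula into directed streamline counts m(v,u) = round(e * S * n(v)) with
per-region voxel counts n(v), so that network construction approximately
recovers the adjacency.

Default group sizes (22 / 21 / 39) mirror a left-focus patient group, a
right-focus patient group and healthy controls. The default effect pattern
diminishes every planted connection in both patient groups relative to
controls, with half the planted connections extra-diminished on the left
and half on the right, so all three group pairs are separable.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .mvpa import LabeledDataset
from .network import (
    DEFAULT_SAMPLES_PER_VOXEL,
    DEFAULT_THRESHOLD,
    FeatureIndexMap,
    FiberCountData,
    build_connectivity,
    vectorize,
)

DEFAULT_GROUP_SIZES = {"left_mtle": 22, "right_mtle": 21, "control": 39}


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic study.

    delta is the planted between-group shift in pooled-SD units (the
    within-group SD is sigma_subj, so the mean shift is delta * sigma_subj).
    """

    n_regions: int = 116
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    density: float = 0.15
    edge_low: float = 0.02
    edge_high: float = 0.5
    n_planted: int = 10
    delta: float = 2.0
    sigma_subj: float = 0.05
    voxel_range: tuple = (200, 2000)
    samples_per_voxel: int = DEFAULT_SAMPLES_PER_VOXEL
    threshold: float = DEFAULT_THRESHOLD
    noise_model: str = "gaussian"  # or "binomial" count-level sampling
    effect_pattern: str = "auto"  # auto | diminished | mixed
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.density <= 1:
            raise ValueError("density must be in (0, 1]")
        if self.delta < 0 or self.sigma_subj <= 0:
            raise ValueError("need delta >= 0 and sigma_subj > 0")
        if self.noise_model not in ("gaussian", "binomial"):
            raise ValueError("noise_model must be 'gaussian' or 'binomial'")
        if self.effect_pattern not in ("auto", "diminished", "mixed"):
            raise ValueError("effect_pattern must be auto|diminished|mixed")
        if len(self.group_sizes) not in (2, 3):
            raise ValueError("generator supports 2 or 3 groups")
        if any(s < 2 for s in self.group_sizes.values()):
            raise ValueError("every group needs >= 2 subjects")
        if not self.edge_low <= self.edge_high or self.edge_low < 0 or self.edge_high > 1:
            raise ValueError("edge strengths must satisfy 0 <= low <= high <= 1")
        f = self.n_regions * (self.n_regions - 1) // 2
        if self.density * f < self.n_planted:
            raise ValueError(
                f"expected nonzero edges ({self.density * f:.0f}) fewer than "
                f"n_planted={self.n_planted}"
            )

    @property
    def labels(self) -> list[str]:
        return list(self.group_sizes)

    @property
    def n_subjects(self) -> int:
        return sum(self.group_sizes.values())

    def to_json(self) -> dict:
        d = {k: getattr(self, k) for k in self.__dataclass_fields__}
        d["voxel_range"] = list(self.voxel_range)
        return d

    @classmethod
    def from_json(cls, d: dict) -> "SyntheticSpec":
        d = dict(d)
        if "voxel_range" in d:
            d["voxel_range"] = tuple(d["voxel_range"])
        return cls(**d)


@dataclass(frozen=True)
class GroundTruth:
    """Planted effects: which features differ between groups and how.

    shifts[label] holds, per planted feature, the group's mean shift in
    units of delta * sigma_subj (0 = at baseline, negative = diminished).
    """

    planted_ids: np.ndarray
    shifts: dict
    group_means: dict  # label -> (R, R) mean adjacency

    def direction(self, group_a: str, group_b: str) -> np.ndarray:
        """Sign of (mean_a - mean_b) per planted feature; 0 if equal."""
        return np.sign(self.shifts[group_a] - self.shifts[group_b]).astype(int)

    def to_json(self) -> dict:
        return {
            "planted_ids": [int(i) for i in self.planted_ids],
            "shifts": {g: [float(v) for v in s] for g, s in self.shifts.items()},
        }


def make_baseline(n_regions: int, density: float, edge_low: float,
                  edge_high: float, seed: int | np.random.Generator) -> np.ndarray:
    """Sparse symmetric baseline mean adjacency with zero diagonal.

    Each upper-triangle edge is nonzero independently with probability
    ``density``; nonzero strengths are uniform on [edge_low, edge_high].
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_feat = n_regions * (n_regions - 1) // 2
    present = rng.random(n_feat) < density
    values = np.where(present, rng.uniform(edge_low, edge_high, n_feat), 0.0)
    out = np.zeros((n_regions, n_regions))
    rows, cols = np.triu_indices(n_regions, k=1)
    out[rows, cols] = values
    out[cols, rows] = values
    return out


def _shift_pattern(spec: SyntheticSpec) -> dict:
    """Per-group shift multipliers (in delta*sigma units) per planted feature.

    Three groups: first two groups (patients) are diminished by 1 on every
    planted feature relative to the last group (controls); even-indexed
    planted features get an extra -1 in the first group, odd-indexed in the
    second, creating the patient-vs-patient contrast. Two groups:
    "diminished" lowers the first group on every feature; "mixed"
    alternates which group is lowered.
    """
    labels = spec.labels
    j = np.arange(spec.n_planted)
    if len(labels) == 3:
        a, b, control = labels
        return {
            a: -1.0 - (j % 2 == 0),
            b: -1.0 - (j % 2 == 1),
            control: np.zeros(spec.n_planted),
        }
    a, b = labels
    pattern = spec.effect_pattern
    if pattern in ("auto", "diminished"):
        return {a: -np.ones(spec.n_planted), b: np.zeros(spec.n_planted)}
    return {a: np.where(j % 2 == 0, -1.0, 0.0),
            b: np.where(j % 2 == 1, -1.0, 0.0)}


def plant_effects(
    baseline: np.ndarray, spec: SyntheticSpec,
    seed: int | np.random.Generator,
) -> tuple[dict, GroundTruth]:
    """Shift a random subset of baseline-nonzero edges between groups.

    Planted edges are drawn only from edges with enough headroom that no
    group mean is clipped below the detection threshold; edges lacking
    headroom have their baseline strength redrawn upward (with a warning).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n_regions = baseline.shape[0]
    index_map = FeatureIndexMap(n_regions)
    base_vec = vectorize(baseline, index_map)
    shifts = _shift_pattern(spec)
    max_drop = max((-s).max() for s in shifts.values()) * spec.delta * spec.sigma_subj
    floor = spec.threshold + 1e-9

    nonzero = np.flatnonzero(base_vec > 0)
    if nonzero.size < spec.n_planted:
        raise ValueError("baseline has fewer nonzero edges than n_planted")
    eligible = nonzero[base_vec[nonzero] - max_drop >= floor]
    if eligible.size >= spec.n_planted:
        planted = rng.choice(eligible, size=spec.n_planted, replace=False)
    else:
        if spec.edge_high < floor + max_drop:
            raise ValueError(
                f"edge_high={spec.edge_high} leaves no headroom for the "
                f"requested effect (needs >= {floor + max_drop:.3g})"
            )
        warnings.warn(
            "not enough headroom among baseline edges; redrawing planted "
            "edge strengths upward", stacklevel=2,
        )
        planted = rng.choice(nonzero, size=spec.n_planted, replace=False)
        base_vec = base_vec.copy()
        base_vec[planted] = rng.uniform(floor + max_drop, spec.edge_high,
                                        spec.n_planted)
    planted = np.sort(planted)

    rows, cols = np.triu_indices(n_regions, k=1)
    group_means = {}
    for label in spec.labels:
        vec = base_vec.copy()
        vec[planted] = np.clip(
            vec[planted] + shifts[label] * spec.delta * spec.sigma_subj, 0.0, 1.0
        )
        mat = np.zeros_like(baseline)
        mat[rows, cols] = vec
        mat[cols, rows] = vec
        group_means[label] = mat
    truth = GroundTruth(planted, shifts, group_means)
    return group_means, truth


def sample_subject(
    mean_matrix: np.ndarray,
    spec: SyntheticSpec,
    seed: int | np.random.Generator,
    subject_id: str | None = None,
    sigma: float | None = None,
) -> FiberCountData:
    """One subject's directed fiber counts from a group mean adjacency.

    Gaussian mode adds symmetric noise to the adjacency then inverts the
    edge formula deterministically; binomial mode draws each directed count
    from Binomial(S * n(v), e) instead. Structural zeros stay zero.
    ``sigma`` overrides spec.sigma_subj (sigma=0 gives a noise-free subject
    whose rebuilt connectivity matches the mean up to count rounding).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    if sigma is None:
        sigma = spec.sigma_subj
    n_regions = mean_matrix.shape[0]
    rows, cols = np.triu_indices(n_regions, k=1)
    s = spec.samples_per_voxel
    voxels = rng.integers(spec.voxel_range[0], spec.voxel_range[1] + 1, n_regions)

    adj = mean_matrix.copy()
    if spec.noise_model == "gaussian" and sigma > 0:
        noise = rng.normal(0.0, sigma, rows.size)
        vals = adj[rows, cols]
        noisy = np.where(vals > 0, np.clip(vals + noise, 0.0, 1.0), 0.0)
        adj[rows, cols] = noisy
        adj[cols, rows] = noisy

    if spec.noise_model == "binomial":
        trials_fwd = (s * voxels[:, None]) * np.ones((1, n_regions), dtype=int)
        counts = rng.binomial(trials_fwd, adj)
    else:
        counts = np.rint(adj * s * voxels[:, None]).astype(np.int64)
    np.fill_diagonal(counts, 0)
    return FiberCountData(counts, voxels, samples_per_voxel=s,
                          subject_id=subject_id)


@dataclass
class SyntheticDataset:
    """Everything one synthetic study produces."""

    spec: SyntheticSpec
    dataset: LabeledDataset
    truth: GroundTruth
    subjects: list  # list of FiberCountData
    manifest: list  # dicts: subject_id, group, counts_path, voxels_path


def generate_dataset(spec: SyntheticSpec,
                     out_dir: str | Path | None = None) -> SyntheticDataset:
    """Generate the full study: subjects, rebuilt feature matrix, truth.

    With ``out_dir`` the per-subject count/voxel files, the manifest TSV,
    the spec JSON and the ground-truth JSON are also written in the exact
    dialects the network-construction readers consume. Fully reproducible
    from ``spec.seed``.
    """
    master = np.random.SeedSequence(spec.seed)
    base_rng, plant_rng, *_ = [np.random.default_rng(s) for s in master.spawn(2)]
    baseline = make_baseline(spec.n_regions, spec.density, spec.edge_low,
                             spec.edge_high, base_rng)
    group_means, truth = plant_effects(baseline, spec, plant_rng)

    index_map = FeatureIndexMap(spec.n_regions)
    subjects: list[FiberCountData] = []
    labels: list[str] = []
    ids: list[str] = []
    k = 0
    for group, size in spec.group_sizes.items():
        for i in range(size):
            sid = f"{group}_{i:03d}"
            rng = np.random.default_rng([spec.seed, 1000 + k])
            subjects.append(sample_subject(group_means[group], spec, rng, sid))
            labels.append(group)
            ids.append(sid)
            k += 1

    x = np.stack([
        vectorize(build_connectivity(s, spec.threshold), index_map)
        for s in subjects
    ])
    dataset = LabeledDataset(x, np.array(labels), index_map, ids)

    manifest = []
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for subj, group in zip(subjects, labels):
            counts_path = out_dir / f"{subj.subject_id}_counts.tsv"
            voxels_path = out_dir / f"{subj.subject_id}_voxels.txt"
            np.savetxt(counts_path, subj.counts, fmt="%d", delimiter="\t")
            np.savetxt(voxels_path, subj.voxels, fmt="%d")
            manifest.append({
                "subject_id": subj.subject_id, "group": group,
                "counts_path": counts_path.name, "voxels_path": voxels_path.name,
            })
        with open(out_dir / "manifest.tsv", "w") as fh:
            fh.write("subject_id\tgroup\tcounts_path\tvoxels_path\n")
            for row in manifest:
                fh.write("{subject_id}\t{group}\t{counts_path}\t{voxels_path}\n"
                         .format(**row))
        with open(out_dir / "ground_truth.json", "w") as fh:
            json.dump(truth.to_json(), fh, indent=1, sort_keys=True)
        with open(out_dir / "spec.json", "w") as fh:
            json.dump(spec.to_json(), fh, indent=1, sort_keys=True)
    else:
        manifest = [{"subject_id": sid, "group": g, "counts_path": None,
                     "voxels_path": None} for sid, g in zip(ids, labels)]
    return SyntheticDataset(spec, dataset, truth, subjects, manifest)
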