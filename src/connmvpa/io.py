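"""File readers/writers and the run configuration.

All tabular artifacts are plain text (TSV/CSV), results are JSON with
sorted keys so reruns with the same seed are byte-identical; result files
embed the configuration snapshot that produced them.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .mvpa import ConsensusResult, LabeledDataset
from .network import (
    ConnectivityMatrix,
    FeatureIndexMap,
    FiberCountData,
    build_connectivity,
    vectorize,
)


def read_counts_matrix(path: str | Path) -> np.ndarray:
    """Dense R x R integer fiber-count matrix, whitespace- or comma-delimited."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline()
    delimiter = "," if "," in first else None
    try:
        m = np.loadtxt(path, delimiter=delimiter)
    except ValueError as err:
        raise ValueError(f"{path}: cannot parse count matrix ({err})") from err
    if np.isnan(m).any():
        raise ValueError(f"{path}: NaN in count matrix")
    return np.rint(m).astype(np.int64)


def read_voxel_counts(path: str | Path) -> np.ndarray:
    """Per-region voxel counts, one integer per line."""
    v = np.loadtxt(path)
    if np.isnan(v).any():
        raise ValueError(f"{path}: NaN in voxel counts")
    return np.rint(np.atleast_1d(v)).astype(np.int64)


def load_manifest(path: str | Path) -> pd.DataFrame:
    """Manifest TSV: subject_id, group, counts_path, voxels_path."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"subject_id", "group", "counts_path", "voxels_path"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: manifest missing column(s) {sorted(missing)}")
    return df


def load_manifest_dataset(
    manifest_path: str | Path,
    threshold: float = 0.01,
    samples_per_voxel: int = 5000,
) -> LabeledDataset:
    """Assemble the subjects x features dataset from a manifest of count files.

    Relative paths in the manifest resolve against the manifest's directory.
    """
    manifest_path = Path(manifest_path)
    df = load_manifest(manifest_path)
    base = manifest_path.parent
    rows, labels, ids = [], [], []
    index_map = None
    for rec in df.itertuples(index=False):
        counts = read_counts_matrix(base / rec.counts_path)
        voxels = read_voxel_counts(base / rec.voxels_path)
        data = FiberCountData(counts, voxels, samples_per_voxel,
                              subject_id=rec.subject_id)
        if index_map is None:
            index_map = FeatureIndexMap(data.n_regions)
        conn = build_connectivity(data, threshold)
        rows.append(vectorize(conn, index_map))
        labels.append(rec.group)
        ids.append(rec.subject_id)
    if not rows:
        raise ValueError(f"{manifest_path}: empty manifest")
    return LabeledDataset(np.stack(rows), np.array(labels), index_map, ids)


def write_connectivity_csv(matrix: ConnectivityMatrix, path: str | Path) -> None:
    np.savetxt(path, matrix.values, fmt="%.8g", delimiter=",")


def write_dataset_csv(dataset: LabeledDataset, region_names: list[str],
                      path: str | Path) -> None:
    """Subjects x features CSV with a header of region-pair names."""
    cols = dataset.index_map.pair_names(region_names)
    df = pd.DataFrame(dataset.x, columns=cols)
    df.insert(0, "group", dataset.y)
    df.insert(0, "subject_id", dataset.subject_ids
              or [f"s{i}" for i in range(dataset.n_subjects)])
    df.to_csv(path, index=False)


def write_edge_list(matrix: np.ndarray, region_names: list[str],
                    path: str | Path) -> None:
    """Nonzero upper-triangle edges as TSV (region_a, region_b, weight)."""
    rows, cols = np.triu_indices(matrix.shape[0], k=1)
    with open(path, "w") as fh:
        fh.write("region_a\tregion_b\tweight\n")
        for v, u in zip(rows, cols):
            if matrix[v, u] != 0:
                fh.write(f"{region_names[v]}\t{region_names[u]}\t{matrix[v, u]:.8g}\n")


def write_consensus_tsv(consensus: ConsensusResult, index_map: FeatureIndexMap,
                        region_names: list[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature_id\tregion_a\tregion_b\tmean_t\tdirection\n")
        for fid, t, d in zip(consensus.feature_ids, consensus.mean_t,
                             consensus.direction):
            v, u = index_map.index_to_pair(int(fid))
            fh.write(f"{fid}\t{region_names[v]}\t{region_names[u]}\t{t:.6g}\t{d:+d}\n")


def write_region_weights_tsv(weights: np.ndarray, region_names: list[str],
                             path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tweight\n")
        for name, w in zip(region_names, weights):
            fh.write(f"{name}\t{w:.6g}\n")


def write_json(payload: dict, path: str | Path,
               config: "RunConfig | None" = None) -> None:
    """Write a result JSON, embedding the producing config snapshot."""
    out = dict(payload)
    if config is not None:
        out["config"] = config.to_json()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(out, fh, indent=1, sort_keys=True)
        fh.write("\n")


@dataclass
class RunConfig:
    """Every knob of one pipeline run, serializable to/from JSON.

    Defaults follow the study protocol: edge threshold tau = 0.01, 5000
    streamline samples per voxel, alpha = 0.05 two-sided pooled t-test,
    LOOCV, 10,000 permutations.
    """

    region_table: str | None = None
    manifest: str | None = None
    out_dir: str = "results"
    threshold: float = 0.01
    samples_per_voxel: int = 5000
    alpha: float = 0.05
    t_variant: str = "pooled"
    fallback_k: int = 10
    lle_k: int | None = None
    lle_d: int | None = None
    reg_eps: float = 1e-3
    svm_c: float = 1.0
    svm_gamma: float | None = None
    cv: str = "loocv"
    kfolds: int = 10
    stratified: bool = True
    n_perm: int = 10_000
    mask_lobes: list = field(default_factory=list)
    seed: int = 0

    def to_json(self) -> dict:
        return asdict(self)

    @classmethod
    def from_json(cls, d: dict) -> "RunConfig":
        known = {k: v for k, v in d.items() if k in cls.__dataclass_fields__}
        return cls(**known)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_json(json.load(fh))

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json(), fh, indent=1, sort_keys=True)
            fh.write("\n")
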