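"""Parcellation metadata and region/feature masking.

The default parcellation is the 116-region automated anatomical labeling
(AAL) atlas. Each region carries a lobe assignment (used e.g. to mask out
all connections incident on temporal-lobe regions) and a hemisphere tag.

Region ids are 0-based in memory; the TSV file format uses 1-based ids,
matching the AAL numbering convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

ALLOWED_LOBES = frozenset(
    {"frontal", "limbic", "parietal", "temporal", "occipital",
     "subcortical", "cerebellum", "vermis"}
)
ALLOWED_HEMISPHERES = frozenset({"L", "R", "M"})


class RegionTableError(ValueError):
    """Malformed region table (ids, lobes or hemispheres invalid)."""


@dataclass(frozen=True)
class RegionTable:
    """Validated parcellation table: region id -> (name, lobe, hemisphere)."""

    frame: pd.DataFrame  # columns: name, lobe, hemisphere; index: region_id 0..R-1

    def __post_init__(self) -> None:
        df = self.frame
        ids = np.asarray(df.index)
        r = len(df)
        if r == 0:
            raise RegionTableError("region table is empty")
        if not np.array_equal(np.sort(ids), np.arange(r)):
            raise RegionTableError(
                f"region ids must be exactly 0..{r - 1} with no gaps or "
                f"duplicates; got {sorted(ids)[:10]}..."
            )
        bad_lobe = set(df["lobe"]) - ALLOWED_LOBES
        if bad_lobe:
            raise RegionTableError(f"unknown lobe token(s): {sorted(bad_lobe)}")
        bad_hemi = set(df["hemisphere"]) - ALLOWED_HEMISPHERES
        if bad_hemi:
            raise RegionTableError(f"unknown hemisphere token(s): {sorted(bad_hemi)}")

    @property
    def n_regions(self) -> int:
        return len(self.frame)

    @property
    def names(self) -> list[str]:
        return list(self.frame["name"])

    def __len__(self) -> int:
        return len(self.frame)


def load_region_table(path: str | Path | None = None) -> RegionTable:
    """Read a region table TSV (columns id, name, lobe, hemisphere).

    File ids are 1-based; they are shifted to 0-based internally. With no
    ``path`` the shipped AAL-116 table is loaded.
    """
    if path is None:
        with resources.as_file(
            resources.files("connmvpa.data") / "aal116.tsv"
        ) as p:
            return load_region_table(p)
    df = pd.read_csv(path, sep="\t", dtype={"id": int, "name": str,
                                            "lobe": str, "hemisphere": str})
    required = {"id", "name", "lobe", "hemisphere"}
    missing = required - set(df.columns)
    if missing:
        raise RegionTableError(f"missing column(s): {sorted(missing)}")
    df = df.set_index(df["id"] - 1).drop(columns="id")
    df.index.name = "region_id"
    return RegionTable(df)


def regions_in_lobes(table: RegionTable, lobes: set[str]) -> set[int]:
    """Region ids whose lobe is in ``lobes`` (both hemispheres)."""
    unknown = set(lobes) - ALLOWED_LOBES
    if unknown:
        raise ValueError(f"unknown lobe token(s): {sorted(unknown)}")
    if not lobes:
        return set()
    sel = table.frame["lobe"].isin(lobes)
    return set(table.frame.index[sel])


def feature_mask(masked_regions: set[int], n_regions: int) -> np.ndarray:
    """Boolean keep-mask over the R(R-1)/2 upper-triangle features.

    Entry is False for every feature (v, u) with v or u in
    ``masked_regions``, True otherwise.
    """
    masked = set(masked_regions)
    out_of_range = [r for r in masked if not 0 <= r < n_regions]
    if out_of_range:
        raise ValueError(
            f"region id(s) out of range 0..{n_regions - 1}: {sorted(out_of_range)}"
        )
    region_masked = np.zeros(n_regions, dtype=bool)
    if masked:
        region_masked[sorted(masked)] = True
    rows, cols = np.triu_indices(n_regions, k=1)
    return ~(region_masked[rows] | region_masked[cols])
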