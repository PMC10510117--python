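"""Regions x samples copy-number matrix and read-depth genotyping.

The read-depth genotyping rule estimates a region's copy number as
``CN = 2 * regional mean RD / genome-wide mean RD`` — the standard
re-genotyping step of read-depth CNV callers, applied on autosomes where the
background is diploid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from cnvpop.io_formats import read_matrix_tsv, write_matrix_tsv


def genotype_from_rd(region_mean_rd, global_mean_rd):
    """Copy number from read depth: 2 * region RD / genome-average RD.

    Accepts scalars or arrays; homogeneous of degree 1 in region RD and
    degree -1 in global RD, so rescaling both leaves CN unchanged.
    """
    global_mean_rd = np.asarray(global_mean_rd, dtype=float)
    if np.any(global_mean_rd <= 0):
        raise ValueError("global_mean_rd must be > 0")
    region_mean_rd = np.asarray(region_mean_rd, dtype=float)
    if np.any(region_mean_rd < 0):
        raise ValueError("region_mean_rd must be >= 0")
    out = 2.0 * region_mean_rd / global_mean_rd
    return float(out) if out.ndim == 0 else out


@dataclass
class CopyNumberMatrix:
    """Real-valued copy numbers with per-sample population labels.

    coords optionally maps region_id -> (chrom, start, end) so records can be
    lifted to genes downstream.
    """

    region_ids: list
    sample_ids: list
    values: np.ndarray  # shape (n_regions, n_samples), >= 0
    groups: Mapping     # sample_id -> population label
    coords: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.region_ids)} regions x {len(self.sample_ids)} samples")
        if np.any(~np.isfinite(self.values)):
            raise ValueError("copy-number matrix contains non-finite entries")
        if np.any(self.values < 0):
            raise ValueError("copy numbers must be >= 0")
        missing = [s for s in self.sample_ids if s not in self.groups]
        if missing:
            raise ValueError(f"samples without a group label: {missing}")
        if len(set(self.groups[s] for s in self.sample_ids)) < 2:
            raise ValueError("need at least 2 populations")

    @property
    def group_vector(self) -> list:
        return [self.groups[s] for s in self.sample_ids]

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.sample_ids)

    def rounded(self) -> "CopyNumberMatrix":
        """Integer-rounded copy (half-to-even), for the exact rational
        worked-example convention."""
        return CopyNumberMatrix(
            region_ids=list(self.region_ids), sample_ids=list(self.sample_ids),
            values=np.round(self.values), groups=dict(self.groups),
            coords=dict(self.coords))

    def write_tsv(self, path) -> None:
        write_matrix_tsv(self.to_dataframe(), path)

    @classmethod
    def read_tsv(cls, path, groups: Mapping, coords: dict | None = None):
        df = read_matrix_tsv(path)
        return cls(region_ids=list(df.index), sample_ids=list(df.columns),
                   values=df.to_numpy(), groups=dict(groups),
                   coords=dict(coords or {}))


def build_matrix(
    regions: Sequence,
    samples: Sequence[str],
    cn_source,
    groups: Mapping,
    default_cn: float = 2.0,
) -> CopyNumberMatrix:
    """Assemble the matrix from merged regions and a CN source.

    regions: objects with region_id/chrom/start/end, already genome-ordered.
    cn_source: mapping (region_id, sample_id) -> CN, or a DataFrame indexed by
    region_id with sample columns; cells absent from the source (non-carriers)
    default to the diploid baseline.
    """
    missing = [s for s in samples if s not in groups]
    if missing:
        raise ValueError(f"samples without a group label: {missing}")
    n_r, n_s = len(regions), len(samples)
    values = np.full((n_r, n_s), float(default_cn))
    if isinstance(cn_source, pd.DataFrame):
        lookup = {
            (rid, s): v
            for rid, row in cn_source.iterrows()
            for s, v in row.items()
            if pd.notna(v)
        }
    else:
        lookup = dict(cn_source)
    for i, r in enumerate(regions):
        for j, s in enumerate(samples):
            v = lookup.get((r.region_id, s))
            if v is not None:
                values[i, j] = float(v)
    coords = {r.region_id: (r.chrom, r.start, r.end) for r in regions}
    return CopyNumberMatrix(
        region_ids=[r.region_id for r in regions], sample_ids=list(samples),
        values=values, groups=dict(groups), coords=coords)
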