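"""Filter CNV calls and merge them across samples into CNV regions (CNVRs).

The merge rule is the classical union rule: within one chromosome (and one
svtype stratum unless cross-type merging is requested), every maximal set of
transitively overlapping call intervals (any >= 1 bp overlap) becomes one
region spanning their union.  Regions then pass a carrier-count filter
(default: at least three carriers in at least one breed) and are partitioned
into breed-shared and breed-specific sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from cnvpop.io_formats import CNVCall, chrom_sort_key


@dataclass(frozen=True)
class FilterThresholds:
    """Call-quality thresholds; all comparisons are strict, as printed by the
    caller-filtering convention (p < 0.01, q0 < 0.5, size > 1 kb)."""

    max_pval: float = 0.01
    max_q0: float = 0.5
    min_size: int = 1000
    min_carriers: int = 3

    def __post_init__(self):
        if self.max_pval <= 0 or self.max_q0 <= 0 or self.max_q0 > 1:
            raise ValueError("max_pval must be > 0 and max_q0 in (0, 1]")
        if self.min_size < 0 or self.min_carriers < 1:
            raise ValueError("min_size must be >= 0 and min_carriers >= 1")


@dataclass
class CNVRegion:
    """A merged region with per-breed carrier sets."""

    region_id: str
    chrom: str
    start: int
    end: int
    svtype: str  # DEL, DUP or MIXED
    carriers: dict = field(default_factory=dict)  # population -> set of sample_ids

    def __post_init__(self):
        if not self.start < self.end:
            raise ValueError(f"require start < end, got [{self.start}, {self.end})")
        if self.svtype not in ("DEL", "DUP", "MIXED"):
            raise ValueError(f"bad svtype {self.svtype!r}")

    @property
    def size(self) -> int:
        return self.end - self.start

    @property
    def carrier_set(self) -> set:
        out: set = set()
        for s in self.carriers.values():
            out |= s
        return out

    @property
    def n_carriers(self) -> int:
        return len(self.carrier_set)


def filter_calls(calls: Iterable[CNVCall], t: FilterThresholds = FilterThresholds()) -> list[CNVCall]:
    """Retain calls with pval < max_pval, q0 < max_q0 and size > min_size
    (all strict); input order preserved."""
    return [
        c for c in calls
        if c.pval < t.max_pval and c.q0 < t.max_q0 and c.size > t.min_size
    ]


def merge_calls(
    calls: Iterable[CNVCall],
    labels: Mapping,
    same_type_only: bool = True,
    known_chroms: Sequence[str] | None = None,
) -> list[CNVRegion]:
    """Union-merge overlapping calls across samples into CNVRegions.

    labels maps sample_id -> population; carriers are grouped by population.
    With same_type_only (default) DEL and DUP are merged in separate strata,
    mirroring separately reported deletion and duplication regions; otherwise
    a single stratum per chromosome is used and regions containing both call
    types are labelled MIXED.
    """
    calls = list(calls)
    if known_chroms is not None:
        known = set(known_chroms)
        for c in calls:
            if c.chrom not in known:
                raise ValueError(f"call on unknown chromosome {c.chrom!r}")
    missing = sorted({c.sample_id for c in calls} - set(labels))
    if missing:
        raise ValueError(f"samples without a population label: {missing}")

    strata: dict[tuple, list[CNVCall]] = {}
    for c in calls:
        key = (c.chrom, c.svtype if same_type_only else None)
        strata.setdefault(key, []).append(c)

    regions: list[CNVRegion] = []
    for (chrom, _sv), group in strata.items():
        group.sort(key=lambda c: (c.start, c.end))
        cur: list[CNVCall] = []
        cur_end = -1
        for c in group:
            if cur and c.start < cur_end:  # >= 1 bp overlap with the union so far
                cur.append(c)
                cur_end = max(cur_end, c.end)
            else:
                if cur:
                    regions.append(_make_region(cur, labels))
                cur = [c]
                cur_end = c.end
        if cur:
            regions.append(_make_region(cur, labels))

    regions.sort(key=lambda r: (chrom_sort_key(r.chrom), r.start, r.end, r.svtype))
    for i, r in enumerate(regions):
        r.region_id = f"CNVR{i + 1:05d}"
    return regions


def _make_region(members: list[CNVCall], labels: Mapping) -> CNVRegion:
    svtypes = {c.svtype for c in members}
    sv = members[0].svtype if len(svtypes) == 1 else "MIXED"
    carriers: dict = {}
    for c in members:
        carriers.setdefault(labels[c.sample_id], set()).add(c.sample_id)
    return CNVRegion(
        region_id="", chrom=members[0].chrom,
        start=min(c.start for c in members), end=max(c.end for c in members),
        svtype=sv, carriers=carriers)


def carrier_filter(
    regions: Iterable[CNVRegion],
    min_carriers: int = 3,
    mode: str = "any_breed",
) -> list[CNVRegion]:
    """Keep regions carried by >= min_carriers individuals in at least one
    breed (any_breed, default) or in every breed (each_breed)."""
    if mode not in ("any_breed", "each_breed"):
        raise ValueError(f"unknown mode {mode!r}; use 'any_breed' or 'each_breed'")
    out = []
    for r in regions:
        counts = [len(s) for s in r.carriers.values()]
        ok = (
            any(c >= min_carriers for c in counts)
            if mode == "any_breed"
            else counts and all(c >= min_carriers for c in counts)
        )
        if ok:
            out.append(r)
    return out


def partition_by_breed(regions: Iterable[CNVRegion]) -> dict:
    """Venn partition: shared (carriers in >= 2 breeds) vs breed-specific."""
    shared: list[CNVRegion] = []
    specific: dict[str, list[CNVRegion]] = {}
    for r in regions:
        pops = [p for p, s in r.carriers.items() if s]
        if len(pops) >= 2:
            shared.append(r)
        elif len(pops) == 1:
            specific.setdefault(pops[0], []).append(r)
    return {"shared": shared, "specific": specific}


SIZE_CLASS_EDGES = (10_000, 50_000)  # [<10 kb, 10-50 kb, >= 50 kb)


def summarize(regions: Sequence[CNVRegion], chrom_lengths: Mapping | None = None) -> dict:
    """Descriptive tables over the final region set.

    Returns a dict with:
      by_svtype      — counts, mean and total sizes per svtype
      size_classes   — counts per svtype in [<10 kb), [10, 50 kb), [>= 50 kb)
      by_chromosome  — per-chromosome counts by svtype
      length_correlation — Pearson r between chromosome length and CNVR count
                           (None unless chrom_lengths given)
    """
    svtypes = sorted({r.svtype for r in regions} | {"DEL", "DUP"})
    df = pd.DataFrame(
        [(r.chrom, r.svtype, r.size) for r in regions],
        columns=["chrom", "svtype", "size"],
    )
    by_svtype = pd.DataFrame(index=svtypes, columns=["count", "mean_size", "total_size"], dtype=float)
    size_classes = pd.DataFrame(
        0, index=svtypes, columns=["lt_10kb", "10_50kb", "ge_50kb"], dtype=int)
    for sv in svtypes:
        sizes = df.loc[df.svtype == sv, "size"]
        by_svtype.loc[sv] = [len(sizes), sizes.mean() if len(sizes) else 0.0, sizes.sum()]
        size_classes.loc[sv] = [
            int((sizes < SIZE_CLASS_EDGES[0]).sum()),
            int(((sizes >= SIZE_CLASS_EDGES[0]) & (sizes < SIZE_CLASS_EDGES[1])).sum()),
            int((sizes >= SIZE_CLASS_EDGES[1]).sum()),
        ]
    by_chrom = (
        df.groupby(["chrom", "svtype"]).size().unstack(fill_value=0)
        if len(df) else pd.DataFrame()
    )
    if not by_chrom.empty:
        by_chrom = by_chrom.loc[sorted(by_chrom.index, key=chrom_sort_key)]

    corr = None
    if chrom_lengths is not None and len(df):
        counts = df.groupby("chrom").size()
        chroms = sorted(chrom_lengths, key=chrom_sort_key)
        x = np.array([chrom_lengths[c] for c in chroms], dtype=float)
        y = np.array([counts.get(c, 0) for c in chroms], dtype=float)
        if len(chroms) >= 3 and np.ptp(x) > 0 and np.ptp(y) > 0:
            corr = float(stats.pearsonr(x, y).statistic)
    return {
        "by_svtype": by_svtype,
        "size_classes": size_classes,
        "by_chromosome": by_chrom,
        "length_correlation": corr,
    }
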