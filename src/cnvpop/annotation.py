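"""CNVR annotation: gene/QTL interval intersection and over-representation.

QTL overlaps follow the "more than 1 kb" convention (strict), gene overlaps
any positive overlap.  Functional over-representation of a hit-gene set
against user-supplied term -> gene-set tables uses the one-sided
hypergeometric tail, with an optional Benjamini-Hochberg correction that is
off by default (raw p < 0.05 is the reporting convention mirrored here).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from cnvpop.io_formats import GenomicFeature, normalize_chrom


@dataclass(frozen=True)
class OverlapRecord:
    region_id: str
    feature_id: str
    kind: str        # "gene" or "qtl"
    overlap_bp: int
    trait_class: str = ""  # QTL trait class, when annotated

    def __post_init__(self):
        if self.overlap_bp < 1:
            raise ValueError("overlap_bp must be >= 1")


def intersect(
    regions: Sequence,
    features: Sequence[GenomicFeature],
    min_overlap: int | None = None,
) -> list[OverlapRecord]:
    """All (region, feature) pairs overlapping by more than min_overlap bp.

    min_overlap is strict (`overlap > min_overlap`); it defaults to 1000 for
    QTL features ("more than 1 kb") and 0 for genes (any >= 1 bp overlap).
    Chromosome names are normalized before matching, and the pairing is done
    with a sorted sweep per chromosome.
    """
    records: list[OverlapRecord] = []
    by_chrom_feats: dict[str, list[GenomicFeature]] = {}
    for f in features:
        by_chrom_feats.setdefault(normalize_chrom(f.chrom), []).append(f)
    for feats in by_chrom_feats.values():
        feats.sort(key=lambda f: (f.start, f.end))

    for r in sorted(regions, key=lambda r: (normalize_chrom(r.chrom), r.start)):
        feats = by_chrom_feats.get(normalize_chrom(r.chrom), ())
        # sweep: features are start-sorted; stop once past the region end
        for f in feats:
            if f.start >= r.end:
                break
            ov = min(r.end, f.end) - max(r.start, f.start)
            thr = min_overlap if min_overlap is not None else (1000 if f.kind == "qtl" else 0)
            if ov > thr:
                records.append(OverlapRecord(
                    region_id=r.region_id, feature_id=f.feature_id,
                    kind=f.kind, overlap_bp=int(ov),
                    trait_class=str(f.attributes.get("trait_class", ""))))
    return records


def overlap_counts(records: Iterable[OverlapRecord]) -> tuple[pd.Series, pd.Series]:
    """(features per region, regions per feature) count tables."""
    df = pd.DataFrame(
        [(x.region_id, x.feature_id) for x in records],
        columns=["region_id", "feature_id"])
    per_region = df.groupby("region_id").feature_id.nunique()
    per_feature = df.groupby("feature_id").region_id.nunique()
    return per_region, per_feature


def overrepresentation(
    hit_genes: set,
    gene_sets: Mapping,
    universe: set,
    alpha: float = 0.05,
    bh_correction: bool = False,
) -> pd.DataFrame:
    """One-sided hypergeometric enrichment of hit_genes against each term.

    For a term annotating K of the N universe genes, with k hits among the
    n = |hit_genes| selected genes, p = P[X >= k], X ~ Hypergeom(N, K, n).
    Returns a term table with counts, p-values and a significance flag at
    `alpha` (on BH-adjusted values when bh_correction is set).
    """
    if not universe:
        raise ValueError("empty gene universe")
    extra = set(hit_genes) - set(universe)
    if extra:
        raise ValueError(f"hit genes outside the universe: {sorted(extra)[:5]}")
    n = len(hit_genes)
    N = len(universe)
    rows = []
    for term, genes in gene_sets.items():
        term_genes = set(genes) & set(universe)
        K = len(term_genes)
        k = len(term_genes & set(hit_genes))
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if K else 1.0
        rows.append((term, N, K, n, k, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["term", "N", "K", "n", "k", "pval"])
    if bh_correction and len(df):
        df["pval_adj"] = stats.false_discovery_control(df["pval"], method="bh")
        df["significant"] = df["pval_adj"] < alpha
    else:
        df["significant"] = df["pval"] < alpha
    return df.sort_values("pval", kind="stable").reset_index(drop=True)
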