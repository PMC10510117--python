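"""Stage 5 — annotate CNVRs with genes and QTLs and test enrichment.

Lays synthetic gene and QTL annotations over the CNVR set (so the stage runs
without external databases), intersects regions with features (genes: any
overlap; QTLs: more than 1 kb), and tests a hit-gene set for hypergeometric
over-representation against synthetic functional terms.
"""

import argparse
from pathlib import Path

import numpy as np
import pandas as pd

from cnvpop.io_formats import read_cnv_calls
from cnvpop.cnvr_builder import filter_calls, merge_calls, carrier_filter
from cnvpop.pipeline import demo_features
from cnvpop.annotation import intersect, overrepresentation


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--results-dir", default="results")
    ap.add_argument("--seed", type=int, default=1)
    args = ap.parse_args()

    sim_dir = Path(args.results_dir) / "01_simulation"
    out = Path(args.results_dir) / "05_annotation"
    out.mkdir(parents=True, exist_ok=True)

    labels_df = pd.read_csv(sim_dir / "labels.tsv", sep="\t")
    labels = dict(zip(labels_df["sample"], labels_df["population"]))
    calls = []
    for p in sorted((sim_dir / "calls").iterdir()):
        calls.extend(read_cnv_calls(p, dialect="cnvnator"))
    regions = carrier_filter(merge_calls(filter_calls(calls), labels), 3)

    genes, qtls = demo_features(regions, seed=args.seed)
    overlaps = intersect(regions, genes) + intersect(regions, qtls)
    pd.DataFrame([
        {"region_id": o.region_id, "feature_id": o.feature_id, "kind": o.kind,
         "overlap_bp": o.overlap_bp, "trait_class": o.trait_class}
        for o in overlaps
    ]).to_csv(out / "overlaps.tsv", sep="\t", index=False)

    # synthetic functional terms over the gene universe
    universe = {g.feature_id for g in genes}
    rng = np.random.default_rng(args.seed)
    ordered = sorted(universe)
    gene_sets = {
        f"TERM{i + 1:02d}": set(rng.choice(ordered, size=12, replace=False))
        for i in range(8)
    }
    hits = {o.feature_id for o in overlaps if o.kind == "gene"}
    enrich = overrepresentation(hits, gene_sets, universe)
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)

    n_gene = sum(o.kind == "gene" for o in overlaps)
    n_qtl = len(overlaps) - n_gene
    print(f"{n_gene} gene overlaps, {n_qtl} QTL overlaps (>1 kb); "
          f"{int(enrich.significant.sum())}/{len(enrich)} terms significant at p<0.05")


if __name__ == "__main__":
    main()
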