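"""End-to-end orchestration: simulate/load -> filter -> merge -> carrier
filter -> partition -> genotype -> V_ST scan -> threshold -> ANOVA/Tukey ->
cluster -> annotate, with a machine-readable run manifest.

Every stage output is a pure function of the inputs and the seed, so a rerun
with the same configuration reproduces every file byte for byte.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from cnvpop.io_formats import (
    GenomicFeature,
    read_cnv_calls,
    read_features,
    write_cnvr_bed,
    write_matrix_tsv,
)
from cnvpop.synthetic_data import SimulationConfig, simulate_dataset, truth_to_dataframe
from cnvpop.cnvr_builder import (
    FilterThresholds,
    filter_calls,
    merge_calls,
    carrier_filter,
    partition_by_breed,
    summarize,
)
from cnvpop.genotype_matrix import build_matrix, genotype_from_rd
from cnvpop.popdiff import (
    vst_scan,
    percentile_threshold,
    gene_level_vst,
    add_anova,
)
from cnvpop.clustering import (
    presence_matrix,
    multiscale_bootstrap,
    edge_table,
    to_newick,
    DEFAULT_R_GRID,
)
from cnvpop.annotation import intersect, overrepresentation

log = logging.getLogger("cnvpop")


@dataclass
class PipelineConfig:
    """Flat configuration for one pipeline run.

    Either `simulation` is set (synthetic mode) or `calls_dir`/`labels_path`
    point at caller output plus a two-column sample/population table.
    """

    simulation: SimulationConfig | None = None
    calls_dir: str | None = None
    labels_path: str | None = None
    genes_path: str | None = None
    qtl_path: str | None = None
    gene_sets_path: str | None = None
    thresholds: FilterThresholds = field(default_factory=FilterThresholds)
    carrier_mode: str = "any_breed"
    same_type_only: bool = True
    percentile: float = 0.98
    alpha: float = 0.01
    gene_level_threshold: bool = True
    round_cn: bool = False
    metric: str = "jaccard"
    nboot: int = 1000
    r_grid: tuple = DEFAULT_R_GRID
    min_qtl_overlap: int = 1000
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        thr = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if sim is not None:
            cfg.simulation = SimulationConfig(**sim)
        if thr is not None:
            cfg.thresholds = FilterThresholds(**thr)
        return cfg


def _read_labels(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    if not {"sample", "population"} <= set(df.columns):
        raise ValueError("labels file needs 'sample' and 'population' columns")
    return dict(zip(df["sample"].astype(str), df["population"].astype(str)))


def _load_calls_dir(calls_dir) -> list:
    calls = []
    for name in sorted(os.listdir(calls_dir)):
        p = Path(calls_dir) / name
        if p.is_file():
            calls.extend(read_cnv_calls(p, dialect="cnvnator"))
    return calls


def _cn_source_from_calls(regions, calls_by_sample) -> dict:
    """Read-depth genotyping of merged regions from the calls themselves:
    CN = 2 x mean normalized RD of a sample's overlapping same-svtype calls
    (the genome-average RD is 1 after normalization)."""
    source: dict = {}
    by_stratum: dict = {}
    for s, calls in calls_by_sample.items():
        for c in calls:
            by_stratum.setdefault((s, c.chrom, c.svtype), []).append(c)
    for r in regions:
        for s in r.carrier_set:
            rds = [
                c.norm_rd
                for c in by_stratum.get((s, r.chrom, r.svtype), ())
                if min(c.end, r.end) - max(c.start, r.start) > 0
            ]
            if rds:
                source[(r.region_id, s)] = genotype_from_rd(float(np.mean(rds)), 1.0)
    return source


def demo_features(regions, seed: int = 0, n_genes: int = 120, n_qtl: int = 30) -> tuple:
    """Synthetic gene and QTL annotations laid over a region set, so the
    annotation stage can run without external databases.  Genes are placed on
    and between regions; QTLs are wide windows with trait classes."""
    rng = np.random.default_rng(np.random.SeedSequence([seed, 99]))
    if not regions:
        return [], []
    genes, qtls = [], []
    traits = ("Production_QTL", "Reproduction_QTL", "Meat_and_Carcass_QTL",
              "Health_QTL", "Wool_QTL")
    picks = rng.choice(len(regions), size=min(n_genes, len(regions)), replace=False)
    for gi, i in enumerate(sorted(picks)):
        r = regions[i]
        on_region = gi % 2 == 0  # half the genes overlap a region, half sit nearby
        span = max(2000, min(30_000, r.size))
        if on_region:
            start = max(0, r.start + int(rng.integers(0, max(1, r.size // 2))))
        else:
            start = r.end + 50_000 + int(rng.integers(0, 100_000))
        genes.append(GenomicFeature(
            feature_id=f"GENE{gi + 1:04d}", kind="gene", chrom=r.chrom,
            start=start, end=start + span, name=f"GENE{gi + 1:04d}"))
    picks = rng.choice(len(regions), size=min(n_qtl, len(regions)), replace=False)
    for qi, i in enumerate(sorted(picks)):
        r = regions[i]
        width = int(rng.integers(50_000, 500_000))
        start = max(0, r.start - int(rng.integers(0, width // 2)))
        qtls.append(GenomicFeature(
            feature_id=f"QTL{qi + 1:04d}", kind="qtl", chrom=r.chrom,
            start=start, end=start + width, name=f"QTL{qi + 1:04d}",
            attributes={"trait_class": str(rng.choice(traits))}))
    return genes, qtls


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Execute every stage and write all outputs under `outdir`.

    Returns the report bundle: regions, partition, records, threshold,
    candidate table, dendrogram root and summary tables.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {}

    # --- inputs -----------------------------------------------------------
    if config.simulation is not None:
        log.info("simulating synthetic landscape (seed=%d)", config.simulation.seed)
        sim = simulate_dataset(config.simulation)
        truth_to_dataframe(sim.truth).to_csv(out / "truth.tsv", sep="\t", index=False)
        calls_by_sample = sim.calls
        labels = sim.labels
        chrom_lengths = dict(zip(config.simulation.chrom_names,
                                 config.simulation.chrom_lengths))
        bundle["simulation"] = sim
    else:
        if not config.calls_dir or not config.labels_path:
            missing = [n for n, v in (("calls_dir", config.calls_dir),
                                      ("labels_path", config.labels_path)) if not v]
            raise ValueError(f"missing required config field(s): {missing}")
        log.info("reading calls from %s", config.calls_dir)
        all_calls = _load_calls_dir(config.calls_dir)
        labels = _read_labels(config.labels_path)
        calls_by_sample = {}
        for c in all_calls:
            calls_by_sample.setdefault(c.sample_id, []).append(c)
        chrom_lengths = None

    pd.DataFrame(sorted(labels.items()), columns=["sample", "population"]).to_csv(
        out / "labels.tsv", sep="\t", index=False)

    # --- filter and merge --------------------------------------------------
    flat_calls = [c for s in sorted(calls_by_sample) for c in calls_by_sample[s]]
    kept = filter_calls(flat_calls, config.thresholds)
    log.info("filter: %d of %d calls pass", len(kept), len(flat_calls))
    regions = merge_calls(kept, labels, same_type_only=config.same_type_only)
    regions = carrier_filter(regions, config.thresholds.min_carriers, config.carrier_mode)
    log.info("merge: %d regions pass the carrier filter", len(regions))
    write_cnvr_bed(regions, out / "cnvr.bed")
    carrier_rows = [
        {"region_id": r.region_id, "population": p, "samples": ",".join(sorted(ss))}
        for r in regions for p, ss in sorted(r.carriers.items())
    ]
    pd.DataFrame(carrier_rows).to_csv(out / "carriers.tsv", sep="\t", index=False)

    partition = partition_by_breed(regions)
    summary = summarize(regions, chrom_lengths)
    bundle.update(regions=regions, partition=partition, summary=summary)
    summary["size_classes"].to_csv(out / "size_classes.tsv", sep="\t")
    if len(summary["by_chromosome"]):
        summary["by_chromosome"].to_csv(out / "by_chromosome.tsv", sep="\t")

    # --- genotype and V_ST scan -------------------------------------------
    samples = sorted(labels)
    cn_source = _cn_source_from_calls(regions, calls_by_sample)
    matrix = build_matrix(regions, samples, cn_source, labels)
    if config.round_cn:
        matrix = matrix.rounded()
    write_matrix_tsv(matrix.to_dataframe(), out / "cn_matrix.tsv")

    records = vst_scan(matrix)
    genes = read_features(config.genes_path, "gene") if config.genes_path else []
    qtls = read_features(config.qtl_path, "qtl") if config.qtl_path else []
    if config.simulation is not None and not genes:
        genes, qtls = demo_features(regions, seed=config.seed)

    gene_vst = gene_level_vst(records, genes) if genes else {}
    if config.gene_level_threshold and gene_vst:
        threshold = percentile_threshold(list(gene_vst.values()), config.percentile)
        above = {g for g, v in gene_vst.items() if v >= threshold}
    else:
        defined = [r.vst for r in records if r.defined]
        threshold = percentile_threshold(defined, config.percentile)
        above = {r.region_id for r in records if r.defined and r.vst >= threshold}
    log.info("V_ST threshold (q=%.2f): %.4f; %d above", config.percentile,
             threshold, len(above))

    add_anova(records, matrix)
    vst_df = pd.DataFrame([
        {
            "region_id": r.region_id, "chrom": r.chrom, "start": r.start,
            "end": r.end, "vst": r.vst, "v_t": r.v_t, "v_s": r.v_s,
            "defined": r.defined, "anova_F": r.anova_F, "anova_p": r.anova_p,
        }
        for r in records
    ])
    vst_df.to_csv(out / "vst.tsv", sep="\t", index=False)
    vst_df[vst_df.defined][["chrom", "start", "vst"]].to_csv(
        out / "manhattan.tsv", sep="\t", index=False)
    if gene_vst:
        pd.DataFrame(
            sorted(gene_vst.items()), columns=["gene", "vst"]
        ).to_csv(out / "gene_vst.tsv", sep="\t", index=False)

    confirmed = [
        r.region_id for r in records
        if r.defined and not math.isnan(r.anova_p) and r.anova_p < config.alpha
    ]
    bundle.update(records=records, threshold=threshold, above_threshold=above,
                  confirmed=confirmed, gene_vst=gene_vst)

    # --- clustering ---------------------------------------------------------
    pres = presence_matrix(regions, samples)
    write_matrix_tsv(pres.to_dataframe(), out / "presence.tsv")
    root = multiscale_bootstrap(
        pres, r_grid=config.r_grid, nboot=config.nboot,
        metric=config.metric, seed=config.seed)
    (out / "tree.nwk").write_text(to_newick(root) + "\n")
    edge_table(root).to_csv(out / "edges.tsv", sep="\t", index=False)
    bundle["tree"] = root

    # --- annotation ---------------------------------------------------------
    overlaps = []
    if genes:
        overlaps += intersect(regions, genes, min_overlap=0)
    if qtls:
        overlaps += intersect(regions, qtls, min_overlap=config.min_qtl_overlap)
    if overlaps:
        pd.DataFrame([
            {"region_id": o.region_id, "feature_id": o.feature_id, "kind": o.kind,
             "overlap_bp": o.overlap_bp, "trait_class": o.trait_class}
            for o in overlaps
        ]).to_csv(out / "overlaps.tsv", sep="\t", index=False)
    enrichment = None
    if config.gene_sets_path and genes:
        sets_df = pd.read_csv(config.gene_sets_path, sep="\t")
        gene_sets = {
            t: set(g) for t, g in sets_df.groupby("term")["gene"].apply(set).items()
        }
        universe = {g.feature_id for g in genes}
        hit = {o.feature_id for o in overlaps if o.kind == "gene"} & universe
        enrichment = overrepresentation(hit, gene_sets, universe)
        enrichment.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    bundle.update(overlaps=overlaps, enrichment=enrichment)

    # --- manifest ------------------------------------------------------------
    from cnvpop import __version__

    manifest = {
        "package": "cnvpop",
        "version": __version__,
        "seed": config.seed,
        "thresholds": asdict(config.thresholds),
        "carrier_mode": config.carrier_mode,
        "same_type_only": config.same_type_only,
        "percentile": config.percentile,
        "alpha": config.alpha,
        "metric": config.metric,
        "nboot": config.nboot,
        "r_grid": list(config.r_grid),
        "n_calls_in": len(flat_calls),
        "n_calls_pass": len(kept),
        "n_regions": len(regions),
        "n_shared": len(partition["shared"]),
        "n_specific": {p: len(v) for p, v in partition["specific"].items()},
        "vst_threshold": threshold,
        "n_above_threshold": len(above),
        "n_confirmed": len(confirmed),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    bundle["manifest"] = manifest
    return bundle
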