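"""Synthetic two-population CNV landscapes with known ground truth.

Emulates the post-calling stage of a two-breed resequencing study: each truth
region is a deletion or duplication segregating in two populations at known
carrier frequencies, a minority of regions being strongly
frequency-differentiated between the populations.  Carriers emit caller-style
CNV calls whose boundaries wobble by about one read-depth bin, a configurable
fraction of calls violate the standard quality filters, and sub-1-kb decoy
calls exercise the size filter.  Copy-number estimates are the true integer
copy number plus Gaussian read-depth noise.  Everything is deterministic
given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from cnvpop.io_formats import CNVCall
from cnvpop.genotype_matrix import CopyNumberMatrix

DEL_COPY_NUMBERS = (0, 1)
DUP_COPY_NUMBERS = (3, 4, 5, 6)


class PlacementError(ValueError):
    """Regions cannot be placed without overlap on the given chromosomes."""


@dataclass(frozen=True)
class TruthRegion:
    region_id: str
    chrom: str
    start: int
    end: int
    svtype: str
    carrier_freq: dict  # population -> fraction in [0, 1]
    carrier_cn: int     # integer copy number of carriers (DEL < 2 < DUP)
    differentiated: bool

    @property
    def size(self) -> int:
        return self.end - self.start


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic landscape.

    Defaults mirror the two-breed design the pipeline targets: 10 individuals
    per population, 26 autosomes, ~5,000 regions of which ~69% are deletions,
    ~92.5% segregate in both populations, and 50 regions carry a carrier
    frequency gap of at least 0.7 between populations.  Boundary jitter is
    one 300-bp caller bin.
    """

    n_samples_per_pop: int = 10
    pop_labels: tuple = ("OL", "PO")
    n_chroms: int = 26
    chrom_lengths: Sequence[int] | None = None  # default: 275 Mb .. 45 Mb ladder
    n_regions: int = 5000
    del_fraction: float = 0.69
    shared_fraction: float = 0.925
    n_differentiated: int = 50
    differentiation_gap: float = 0.7
    min_size: int = 1200          # bp; log-scale size draw, median < 10 kb
    max_size: int = 400_000       # bp
    size_log10_mean: float = 3.845  # ~7 kb median
    size_log10_sd: float = 0.40
    boundary_jitter_sd: float = 300.0  # bp, one caller bin
    rd_noise_sd: float = 0.25     # copy-number units
    bin_size: int = 300           # bp
    pval_violation_rate: float = 0.05
    q0_violation_rate: float = 0.05
    decoy_fraction: float = 0.05  # decoy (<1 kb) calls per real call
    seed: int = 0

    def __post_init__(self):
        for name in ("del_fraction", "shared_fraction", "pval_violation_rate",
                     "q0_violation_rate", "decoy_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0,1], got {v}")
        if not 0.0 < self.differentiation_gap <= 0.9:
            raise ValueError("differentiation_gap must be in (0, 0.9]")
        for name in ("n_samples_per_pop", "n_chroms", "n_regions", "bin_size"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.n_differentiated > self.n_regions:
            raise ValueError("n_differentiated must be <= n_regions")
        if self.chrom_lengths is None:
            # linearly decreasing ladder so CNVR count vs length is probeable
            self.chrom_lengths = [
                int(x) for x in np.linspace(275e6, 45e6, self.n_chroms)
            ]
        if len(self.chrom_lengths) != self.n_chroms:
            raise ValueError("chrom_lengths length must equal n_chroms")

    @property
    def chrom_names(self) -> list[str]:
        return [f"chr{i + 1}" for i in range(self.n_chroms)]

    @property
    def sample_ids(self) -> list[str]:
        return [
            f"{pop}-{i + 1}"
            for pop in self.pop_labels
            for i in range(self.n_samples_per_pop)
        ]

    @property
    def labels(self) -> dict:
        return {s: s.rsplit("-", 1)[0] for s in self.sample_ids}


def _draw_sizes(rng: np.random.Generator, n: int, cfg: SimulationConfig) -> np.ndarray:
    """Log10-normal sizes truncated to [min_size, max_size] (rejection)."""
    lo, hi = math.log10(cfg.min_size), math.log10(cfg.max_size)
    out = np.empty(n)
    filled = 0
    while filled < n:
        draw = rng.normal(cfg.size_log10_mean, cfg.size_log10_sd, size=2 * (n - filled))
        ok = draw[(draw >= lo) & (draw <= hi)]
        take = min(len(ok), n - filled)
        out[filled:filled + take] = ok[:take]
        filled += take
    return np.round(10 ** out).astype(int)


def _place_nonoverlapping(rng, sizes: np.ndarray, chrom_len: int) -> np.ndarray:
    """Uniformly place len(sizes) disjoint intervals on [0, chrom_len)."""
    total = int(sizes.sum())
    free = chrom_len - total
    if free <= 0:
        raise PlacementError(
            f"cannot place {len(sizes)} regions totalling {total} bp on a "
            f"{chrom_len} bp chromosome; request fewer or smaller regions")
    gaps = np.sort(rng.uniform(0, free, size=len(sizes)))
    starts = (gaps + np.concatenate(([0], np.cumsum(sizes[:-1])))).astype(int)
    return starts


def simulate_truth(config: SimulationConfig) -> list[TruthRegion]:
    """Draw the ground-truth region set (deterministic given config.seed)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 0]))
    cfg = config
    n = cfg.n_regions
    p1, p2 = cfg.pop_labels[0], cfg.pop_labels[1]

    n_del = round(n * cfg.del_fraction)
    svtypes = np.array(["DEL"] * n_del + ["DUP"] * (n - n_del))
    rng.shuffle(svtypes)

    n_shared = round(n * cfg.shared_fraction)
    if cfg.n_differentiated > n_shared:
        raise ValueError("n_differentiated exceeds the shared-region count")
    n_specific = n - n_shared
    # category codes: 0 shared, 1 specific-to-pop1, 2 specific-to-pop2, 3 differentiated
    cats = np.zeros(n, dtype=int)
    cats[n_shared:] = np.where(np.arange(n_specific) % 2 == 0, 1, 2)
    diff_idx = rng.choice(n_shared, size=cfg.n_differentiated, replace=False)
    cats[diff_idx] = 3
    rng.shuffle(cats)

    freqs = np.zeros((n, 2))
    gap = cfg.differentiation_gap
    for i in range(n):
        if cats[i] == 0:
            base = rng.uniform(0.3, 0.9)
            f1 = float(np.clip(base + rng.uniform(-0.05, 0.05), 0.05, 1.0))
            f2 = float(np.clip(base + rng.uniform(-0.05, 0.05), 0.05, 1.0))
        elif cats[i] == 3:
            # near-swept in the favored breed, rare in the other; the gap is
            # at least the configured minimum by construction
            f_high = rng.uniform(max(0.9, gap + 0.06), 1.0)
            f_low = rng.uniform(0.05, min(0.2, f_high - gap))
            if rng.random() < 0.5:
                f1, f2 = f_high, f_low
            else:
                f1, f2 = f_low, f_high
        elif cats[i] == 1:
            # breed-private regions are recent variants at low-moderate
            # frequency, so the flagged differentiated set stays the
            # strongest between-breed signal
            f1, f2 = rng.uniform(0.3, 0.5), 0.0
        else:
            f1, f2 = 0.0, rng.uniform(0.3, 0.5)
        freqs[i] = (f1, f2)

    carrier_cns = np.where(
        svtypes == "DEL",
        rng.choice(DEL_COPY_NUMBERS, size=n),
        rng.choice(DUP_COPY_NUMBERS, size=n),
    )

    sizes = _draw_sizes(rng, n, cfg)
    lengths = np.asarray(cfg.chrom_lengths, dtype=float)
    chrom_idx = rng.choice(cfg.n_chroms, size=n, p=lengths / lengths.sum())

    # place per (chromosome, svtype) stratum so strata stay internally disjoint
    starts = np.zeros(n, dtype=int)
    for ci in range(cfg.n_chroms):
        for sv in ("DEL", "DUP"):
            mask = (chrom_idx == ci) & (svtypes == sv)
            if not mask.any():
                continue
            starts[mask] = _place_nonoverlapping(
                rng, sizes[mask], cfg.chrom_lengths[ci])

    order = np.lexsort((starts, chrom_idx))
    regions = []
    for rank, i in enumerate(order):
        regions.append(TruthRegion(
            region_id=f"T{rank + 1:05d}",
            chrom=cfg.chrom_names[chrom_idx[i]],
            start=int(starts[i]),
            end=int(starts[i] + sizes[i]),
            svtype=str(svtypes[i]),
            carrier_freq={p1: float(freqs[i, 0]), p2: float(freqs[i, 1])},
            carrier_cn=int(carrier_cns[i]),
            differentiated=bool(cats[i] == 3),
        ))
    return regions


def truth_to_dataframe(truth: Sequence[TruthRegion]) -> pd.DataFrame:
    pops = sorted(truth[0].carrier_freq) if truth else []
    rows = [
        {
            "region_id": t.region_id, "chrom": t.chrom, "start": t.start,
            "end": t.end, "svtype": t.svtype, "carrier_cn": t.carrier_cn,
            "differentiated": t.differentiated,
            **{f"freq_{p}": t.carrier_freq[p] for p in pops},
        }
        for t in truth
    ]
    return pd.DataFrame(rows)


def draw_carriers(truth: Sequence[TruthRegion], config: SimulationConfig) -> pd.DataFrame:
    """Bernoulli carrier assignment: boolean regions x samples table."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    samples = config.sample_ids
    labels = config.labels
    probs = np.array([
        [t.carrier_freq[labels[s]] for s in samples] for t in truth
    ])
    values = rng.random(probs.shape) < probs
    return pd.DataFrame(values, index=[t.region_id for t in truth], columns=samples)


def _snap(x: np.ndarray, bin_size: int) -> np.ndarray:
    return (np.round(x / bin_size) * bin_size).astype(int)


def emit_calls(
    truth: Sequence[TruthRegion],
    carriers: pd.DataFrame,
    config: SimulationConfig,
) -> dict:
    """Per-sample caller-style calls: one call per carrier with bin-snapped
    Gaussian boundary jitter, quality fields with a configured violation
    fraction, plus sub-1-kb decoy calls.  Returns sample_id -> list of calls.
    """
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 2]))
    chrom_len = dict(zip(cfg.chrom_names, cfg.chrom_lengths))
    calls: dict[str, list[CNVCall]] = {s: [] for s in cfg.sample_ids}
    n_real = 0
    for t in truth:
        carrier_samples = [s for s in carriers.columns if carriers.at[t.region_id, s]]
        for s in carrier_samples:
            jit = rng.normal(0.0, cfg.boundary_jitter_sd, size=2)
            ds, de = _snap(jit, cfg.bin_size)
            start = max(0, t.start + int(ds))
            end = min(chrom_len[t.chrom], t.end + int(de))
            if end - start < cfg.bin_size:  # jitter collapsed the interval
                end = start + cfg.bin_size
            if cfg.pval_violation_rate > 0 and rng.random() < cfg.pval_violation_rate:
                pval = rng.uniform(0.01, 1.0)
            else:
                pval = 10 ** rng.uniform(-12, math.log10(0.0099))
            if cfg.q0_violation_rate > 0 and rng.random() < cfg.q0_violation_rate:
                q0 = rng.uniform(0.5, 1.0)
            else:
                q0 = rng.uniform(0.0, 0.4999)
            norm_rd = max(0.0, (t.carrier_cn + rng.normal(0, cfg.rd_noise_sd)) / 2.0)
            calls[s].append(CNVCall(
                sample_id=s, chrom=t.chrom, start=start, end=end,
                svtype=t.svtype, norm_rd=norm_rd, pval=pval, q0=q0))
            n_real += 1

    n_decoys = round(cfg.decoy_fraction * n_real)
    lengths = np.asarray(cfg.chrom_lengths, dtype=float)
    for _ in range(n_decoys):
        s = cfg.sample_ids[rng.integers(len(cfg.sample_ids))]
        ci = rng.choice(cfg.n_chroms, p=lengths / lengths.sum())
        size = int(rng.choice([cfg.bin_size, 2 * cfg.bin_size, 3 * cfg.bin_size]))
        size = min(size, 999)  # decoys must fail the strict >1 kb size filter
        start = int(rng.integers(0, cfg.chrom_lengths[ci] - size))
        sv = "DEL" if rng.random() < cfg.del_fraction else "DUP"
        cn = 1 if sv == "DEL" else 3
        calls[s].append(CNVCall(
            sample_id=s, chrom=cfg.chrom_names[ci], start=start, end=start + size,
            svtype=sv, norm_rd=cn / 2.0,
            pval=10 ** rng.uniform(-12, math.log10(0.0099)),
            q0=rng.uniform(0.0, 0.4999)))

    for s in calls:
        calls[s].sort(key=lambda c: (c.chrom, c.start, c.end))
    return calls


def emit_copy_numbers(
    truth: Sequence[TruthRegion],
    carriers: pd.DataFrame,
    config: SimulationConfig,
) -> CopyNumberMatrix:
    """True integer copy number (2 for non-carriers) plus Gaussian read-depth
    noise, truncated at zero."""
    cfg = config
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 3]))
    samples = list(carriers.columns)
    cn_true = np.where(
        carriers.to_numpy(),
        np.array([t.carrier_cn for t in truth])[:, None],
        2.0,
    ).astype(float)
    values = cn_true + rng.normal(0.0, cfg.rd_noise_sd, size=cn_true.shape)
    np.maximum(values, 0.0, out=values)
    coords = {t.region_id: (t.chrom, t.start, t.end) for t in truth}
    return CopyNumberMatrix(
        region_ids=[t.region_id for t in truth],
        sample_ids=samples,
        values=values,
        groups=config.labels,
        coords=coords,
    )


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    truth: list
    carriers: pd.DataFrame
    calls: dict           # sample_id -> list of CNVCall
    cn_matrix: CopyNumberMatrix
    labels: dict          # sample_id -> population


def simulate_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Run the whole generator: truth, carriers, calls and the CN matrix."""
    truth = simulate_truth(config)
    carriers = draw_carriers(truth, config)
    calls = emit_calls(truth, carriers, config)
    cn = emit_copy_numbers(truth, carriers, config)
    return SimulatedDataset(
        config=config, truth=truth, carriers=carriers, calls=calls,
        cn_matrix=cn, labels=config.labels)


def is_well_supported(region: TruthRegion, config: SimulationConfig,
                      min_expected: float = 5.0) -> bool:
    """True when the expected carrier count is >= min_expected in every
    population, i.e. the region should comfortably clear the carrier filter."""
    return all(
        f * config.n_samples_per_pop >= min_expected
        for f in region.carrier_freq.values()
    )


def recovery_rate(truth: Sequence[TruthRegion], regions,
                  reciprocal: float = 0.5) -> float:
    """Fraction of truth regions matched by a same-svtype merged region with
    reciprocal overlap >= `reciprocal` of both lengths."""
    by_stratum: dict[tuple, list] = {}
    for r in regions:
        by_stratum.setdefault((r.chrom, r.svtype), []).append((r.start, r.end))
    hit = 0
    for t in truth:
        for (s, e) in by_stratum.get((t.chrom, t.svtype), ()):
            ov = min(e, t.end) - max(s, t.start)
            if ov > 0 and ov >= reciprocal * (e - s) and ov >= reciprocal * t.size:
                hit += 1
                break
    return hit / len(truth) if truth else float("nan")
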