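"""Population differentiation of copy number: V_ST scan with ANOVA/Tukey.

V_ST = (V_T - V_S) / V_T, where V_T is the variance of the pooled
copy-number vector over all individuals and V_S the unweighted mean of the
within-population variances.  Both variances use the unbiased (n-1)
estimator: with 10+10 integer copy-number configurations this convention
yields exact small-denominator rationals (e.g. 8/27, 25/63), matching the
printed worked examples the scan is validated against.  V_ST is at most 1,
undefined when V_T = 0 (all copy numbers equal), and may be negative (V_S >
V_T); negative values are reported as-is.

Candidate regions or genes above the nearest-rank 98th-percentile threshold
are confirmed by one-way fixed-effects ANOVA, with Tukey's HSD post hoc from
the studentized-range distribution (Tukey-Kramer form when group sizes
differ); for two groups the Tukey p-value coincides with the ANOVA p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy import stats

from cnvpop.genotype_matrix import CopyNumberMatrix


@dataclass
class VstRecord:
    region_id: str
    vst: float          # nan when undefined (V_T == 0)
    v_t: float          # total variance, copy-number^2 units
    v_s: float          # mean within-group variance
    defined: bool
    chrom: str = ""
    start: int = -1
    end: int = -1
    genes: list = field(default_factory=list)
    anova_F: float = math.nan
    anova_p: float = math.nan
    tukey_p: dict = field(default_factory=dict)


def _group_arrays(values, groups) -> dict:
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    if values.shape != groups.shape:
        raise ValueError("values and groups must have equal length")
    if not np.all(np.isfinite(values)):
        raise ValueError("values must be finite")
    out = {}
    for g in dict.fromkeys(groups.tolist()):  # preserve first-seen order
        out[g] = values[groups == g]
    if len(out) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in out.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    return out


def vst(values: Sequence[float], groups: Sequence) -> VstRecord:
    """V_ST of one copy-number vector split by population labels."""
    by_group = _group_arrays(values, groups)
    pooled = np.asarray(values, dtype=float)
    v_t = float(np.var(pooled, ddof=1))
    v_s = float(np.mean([np.var(v, ddof=1) for v in by_group.values()]))
    if v_t == 0.0:
        return VstRecord(region_id="", vst=math.nan, v_t=0.0, v_s=v_s, defined=False)
    return VstRecord(region_id="", vst=(v_t - v_s) / v_t, v_t=v_t, v_s=v_s, defined=True)


def vst_scan(matrix: CopyNumberMatrix) -> list[VstRecord]:
    """One V_ST record per region, in the matrix's genome order.

    Vectorized over rows; undefined records (constant rows) are retained but
    flagged so thresholding can skip them.
    """
    groups = np.asarray(matrix.group_vector)
    uniq = list(dict.fromkeys(groups.tolist()))
    X = matrix.values
    n = X.shape[1]
    if n < 4:
        raise ValueError("need >= 2 samples per group")
    for g in uniq:
        if (groups == g).sum() < 2:
            raise ValueError(f"group {g!r} has fewer than 2 samples")
    v_t = X.var(axis=1, ddof=1)
    within = np.stack([X[:, groups == g].var(axis=1, ddof=1) for g in uniq])
    v_s = within.mean(axis=0)
    records = []
    for i, rid in enumerate(matrix.region_ids):
        defined = v_t[i] > 0.0
        val = (v_t[i] - v_s[i]) / v_t[i] if defined else math.nan
        chrom, start, end = matrix.coords.get(rid, ("", -1, -1))
        records.append(VstRecord(
            region_id=rid, vst=float(val), v_t=float(v_t[i]), v_s=float(v_s[i]),
            defined=bool(defined), chrom=chrom, start=start, end=end))
    return records


def percentile_threshold(values: Sequence[float], q: float = 0.98) -> float:
    """Nearest-rank percentile: sort ascending, return the element at rank
    ceil(q * n).  Values >= the returned threshold count as above threshold."""
    vals = sorted(float(v) for v in values if not math.isnan(v))
    if not vals:
        raise ValueError("percentile of an empty value list")
    if not 0.0 < q <= 1.0:
        raise ValueError("q must be in (0, 1]")
    rank = max(1, math.ceil(q * len(vals)))
    return vals[rank - 1]


def gene_level_vst(records: Sequence[VstRecord], genes: Sequence) -> dict:
    """Lift region V_ST to genes: each gene overlapping >= 1 defined region by
    >= 1 bp gets the maximum V_ST over the regions it overlaps.

    Gene/region chromosome names are matched after normalization, so mixed
    'chr1'/'1' sources agree.
    """
    from cnvpop.io_formats import normalize_chrom

    by_chrom: dict[str, list[VstRecord]] = {}
    for r in records:
        if r.defined and r.chrom:
            by_chrom.setdefault(normalize_chrom(r.chrom), []).append(r)
    out: dict[str, float] = {}
    for g in genes:
        best = None
        for r in by_chrom.get(normalize_chrom(g.chrom), ()):
            if min(r.end, g.end) - max(r.start, g.start) > 0:
                if best is None or r.vst > best:
                    best = r.vst
        if best is not None:
            out[g.feature_id] = best
    return out


def anova_tukey(values: Sequence[float], groups: Sequence) -> tuple:
    """One-way fixed-effects ANOVA with Tukey HSD post hoc.

    Returns (F, p, tukey_p) where tukey_p maps each group pair to its
    studentized-range p-value.  Unequal group sizes use the Tukey-Kramer
    standard error.  MSE = 0 with MSB > 0 gives F = inf and p = 0; all values
    identical gives nan F and p (undefined).
    """
    by_group = _group_arrays(values, groups)
    k = len(by_group)
    ns = {g: len(v) for g, v in by_group.items()}
    N = sum(ns.values())
    means = {g: float(np.mean(v)) for g, v in by_group.items()}
    grand = float(np.mean(np.asarray(values, dtype=float)))
    ssb = sum(ns[g] * (means[g] - grand) ** 2 for g in by_group)
    sse = sum(float(np.sum((v - means[g]) ** 2)) for g, v in by_group.items())
    df_b, df_e = k - 1, N - k
    msb, mse = ssb / df_b, sse / df_e

    pairs = [
        (a, b)
        for i, a in enumerate(by_group)
        for b in list(by_group)[i + 1:]
    ]
    if mse == 0.0:
        if msb == 0.0:
            return math.nan, math.nan, {p: math.nan for p in pairs}
        return math.inf, 0.0, {
            p: (0.0 if means[p[0]] != means[p[1]] else 1.0) for p in pairs
        }

    F = msb / mse
    p = float(stats.f.sf(F, df_b, df_e))
    tukey = {}
    for a, b in pairs:
        se = math.sqrt(mse / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
        q = abs(means[a] - means[b]) / se
        tukey[(a, b)] = float(stats.studentized_range.sf(q, k, df_e))
    return F, p, tukey


def add_anova(records: Sequence[VstRecord], matrix: CopyNumberMatrix) -> None:
    """Attach ANOVA/Tukey statistics to records in place (matched by row)."""
    index = {rid: i for i, rid in enumerate(matrix.region_ids)}
    gv = matrix.group_vector
    for r in records:
        i = index[r.region_id]
        r.anova_F, r.anova_p, r.tukey_p = anova_tukey(matrix.values[i], gv)
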