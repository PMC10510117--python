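"""Call filtering, union-merging (against a per-base sweep oracle), carrier
filtering and breed partitioning."""

import itertools

import numpy as np
import pytest

from cnvpop.io_formats import CNVCall
from cnvpop.cnvr_builder import (
    CNVRegion,
    FilterThresholds,
    filter_calls,
    merge_calls,
    carrier_filter,
    partition_by_breed,
    summarize,
)


def _call(sample, chrom, start, end, svtype="DEL", pval=1e-6, q0=0.0):
    return CNVCall(sample_id=sample, chrom=chrom, start=start, end=end,
                   svtype=svtype, pval=pval, q0=q0)


LABELS = {s: ("OL" if s.startswith("OL") else "PO")
          for s in [f"OL-{i}" for i in range(1, 11)] + [f"PO-{i}" for i in range(1, 11)]}


class TestFilterCalls:
    def test_size_exactly_1kb_removed(self):
        c = _call("OL-1", "chr1", 0, 1000)
        assert filter_calls([c]) == []
        assert filter_calls([_call("OL-1", "chr1", 0, 1001)]) != []

    def test_crossed_truth_table_keeps_only_full_pass(self):
        # all 8 combinations of (pval pass/fail, q0 pass/fail, size pass/fail)
        calls = [
            _call("OL-1", "chr1", i * 10_000, i * 10_000 + (5000 if size_ok else 500),
                  pval=0.001 if p_ok else 0.5, q0=0.1 if q_ok else 0.9)
            for i, (p_ok, q_ok, size_ok) in enumerate(
                itertools.product([True, False], repeat=3))
        ]
        kept = filter_calls(calls)
        assert len(kept) == 1
        assert (kept[0].pval, kept[0].q0, kept[0].size) == (0.001, 0.1, 5000)

    def test_boundary_values_are_strict(self):
        at_threshold = _call("OL-1", "chr1", 0, 2000, pval=0.01, q0=0.5)
        assert filter_calls([at_threshold]) == []

    def test_vacuous_thresholds_keep_everything(self):
        calls = [_call("OL-1", "chr1", 0, 500, pval=0.9, q0=0.99)]
        t = FilterThresholds(max_pval=1.0, max_q0=1.0, min_size=0)
        assert filter_calls(calls, t) == calls


def sweep_oracle(calls):
    """Per-base coverage oracle on a small genome: mark every covered base per
    (chrom, svtype) stratum and extract maximal runs."""
    regions = set()
    strata = {}
    for c in calls:
        strata.setdefault((c.chrom, c.svtype), []).append(c)
    for (chrom, sv), group in strata.items():
        hi = max(c.end for c in group)
        covered = np.zeros(hi, dtype=np.int8)
        for c in group:
            covered[c.start:c.end] = 1
        edges = np.flatnonzero(np.diff(np.concatenate(([0], covered, [0]))))
        for s, e in zip(edges[0::2], edges[1::2]):
            regions.add((chrom, sv, int(s), int(e)))
    return regions


def _random_calls(rng, n, n_chroms=3, genome=1_000_000):
    calls = []
    for i in range(n):
        start = int(rng.integers(0, genome - 20_000))
        size = int(rng.integers(1100, 20_000))
        calls.append(_call(
            f"OL-{int(rng.integers(1, 11))}", f"chr{int(rng.integers(1, n_chroms + 1))}",
            start, start + size, svtype="DEL" if rng.random() < 0.7 else "DUP"))
    return calls


class TestMergeCalls:
    def test_textbook_union(self):
        calls = [_call("OL-1", "chr1", 1000, 5000), _call("PO-1", "chr1", 4000, 9000)]
        (r,) = merge_calls(calls, LABELS)
        assert (r.start, r.end, r.n_carriers) == (1000, 9000, 2)
        assert r.carriers == {"OL": {"OL-1"}, "PO": {"PO-1"}}

    def test_strata_kept_separate_by_default(self):
        calls = [_call("OL-1", "chr1", 1000, 2000, "DEL"),
                 _call("PO-1", "chr1", 1500, 3000, "DUP")]
        regions = merge_calls(calls, LABELS, same_type_only=True)
        assert len(regions) == 2
        assert {r.svtype for r in regions} == {"DEL", "DUP"}

    def test_cross_type_merge_labels_mixed(self):
        calls = [_call("OL-1", "chr1", 1000, 2000, "DEL"),
                 _call("PO-1", "chr1", 1500, 3000, "DUP")]
        (r,) = merge_calls(calls, LABELS, same_type_only=False)
        assert r.svtype == "MIXED" and (r.start, r.end) == (1000, 3000)

    def test_touching_intervals_do_not_merge(self):
        calls = [_call("OL-1", "chr1", 1000, 2001), _call("PO-1", "chr1", 2001, 4000)]
        assert len(merge_calls(calls, LABELS)) == 2

    def test_matches_per_base_sweep_oracle(self):
        rng = np.random.default_rng(21)
        calls = _random_calls(rng, 500)
        got = {(r.chrom, r.svtype, r.start, r.end) for r in merge_calls(calls, LABELS)}
        assert got == sweep_oracle(calls)

    def test_idempotent_on_own_output(self):
        rng = np.random.default_rng(22)
        regions = merge_calls(_random_calls(rng, 200), LABELS)
        pseudo = [
            _call(next(iter(r.carrier_set)), r.chrom, r.start, r.end, r.svtype)
            for r in regions
        ]
        again = merge_calls(pseudo, LABELS)
        assert [(r.chrom, r.svtype, r.start, r.end) for r in again] == \
               [(r.chrom, r.svtype, r.start, r.end) for r in regions]

    def test_union_conservation(self):
        rng = np.random.default_rng(23)
        calls = _random_calls(rng, 300)
        regions = merge_calls(calls, LABELS)
        index = {}
        for r in regions:
            index.setdefault((r.chrom, r.svtype), []).append(r)
        for c in calls:
            hits = [
                r for r in index[(c.chrom, c.svtype)]
                if r.start <= c.start and c.end <= r.end
            ]
            assert len(hits) == 1

    def test_unknown_chromosome_rejected(self):
        with pytest.raises(ValueError, match="chrUn"):
            merge_calls([_call("OL-1", "chrUn", 0, 2000)], LABELS,
                        known_chroms=["chr1"])

    def test_missing_label_rejected(self):
        with pytest.raises(ValueError, match="XX-1"):
            merge_calls([_call("XX-1", "chr1", 0, 2000)], LABELS)


def _region(ol=0, po=0, start=1000, end=2000, chrom="chr1", svtype="DEL"):
    return CNVRegion(
        region_id="r", chrom=chrom, start=start, end=end, svtype=svtype,
        carriers={"OL": {f"OL-{i}" for i in range(1, ol + 1)},
                  "PO": {f"PO-{i}" for i in range(1, po + 1)}})


class TestCarrierFilterAndPartition:
    def test_any_vs_each_breed(self):
        r = _region(ol=2, po=4)
        assert carrier_filter([r], 3, "any_breed") == [r]
        assert carrier_filter([r], 3, "each_breed") == []

    def test_single_breed_carriage_counts(self):
        r = _region(ol=3, po=0)
        assert carrier_filter([r], 3, "any_breed") == [r]

    def test_unknown_mode_rejected(self):
        with pytest.raises(ValueError, match="mode"):
            carrier_filter([_region(ol=3)], 3, "either")

    def test_matches_recount_oracle(self, small_sim):
        from cnvpop.cnvr_builder import filter_calls, merge_calls

        calls = [c for s in small_sim.calls for c in small_sim.calls[s]]
        regions = merge_calls(filter_calls(calls), small_sim.labels)
        survivors = carrier_filter(regions, 3, "any_breed")
        expected = [
            r for r in regions
            if max(len(s) for s in r.carriers.values()) >= 3
        ]
        assert survivors == expected

    def test_partition_is_a_partition(self):
        regions = [_region(ol=5, po=0), _region(ol=1, po=1), _region(ol=0, po=2)]
        part = partition_by_breed(regions)
        assert part["specific"]["OL"] == [regions[0]]
        assert part["shared"] == [regions[1]]
        assert part["specific"]["PO"] == [regions[2]]
        total = len(part["shared"]) + sum(len(v) for v in part["specific"].values())
        assert total == len(regions)


class TestSummarize:
    def test_size_class_histogram(self):
        regions = [_region(ol=3, start=0, end=2000),
                   _region(ol=3, start=10_000, end=30_000),
                   _region(ol=3, start=100_000, end=300_000)]
        s = summarize(regions)
        assert s["size_classes"].loc["DEL"].tolist() == [1, 1, 1]

    def test_single_svtype_other_rows_zero(self):
        s = summarize([_region(ol=3, svtype="DUP", start=0, end=5000)])
        assert s["size_classes"].loc["DEL"].sum() == 0
        assert s["by_svtype"].loc["DEL", "count"] == 0

    def test_count_tracks_chromosome_length(self, small_sim):
        from cnvpop.cnvr_builder import filter_calls, merge_calls

        calls = [c for s in small_sim.calls for c in small_sim.calls[s]]
        regions = carrier_filter(
            merge_calls(filter_calls(calls), small_sim.labels), 3, "any_breed")
        lengths = dict(zip(small_sim.config.chrom_names, small_sim.config.chrom_lengths))
        s = summarize(regions, lengths)
        assert s["length_correlation"] > 0.5
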