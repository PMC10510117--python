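"""Presence matrix, Jaccard distance, UPGMA and multiscale bootstrap."""

import numpy as np
import pytest
from scipy.cluster.hierarchy import average
from scipy.spatial.distance import squareform

from cnvpop.cnvr_builder import CNVRegion
from cnvpop.clustering import (
    PresenceMatrix,
    presence_matrix,
    binary_distance,
    upgma,
    tree_edges,
    multiscale_bootstrap,
    edge_table,
    to_newick,
)


def _region(rid, carriers_ol=(), carriers_po=()):
    return CNVRegion(region_id=rid, chrom="chr1", start=1000, end=2000,
                     svtype="DEL",
                     carriers={"OL": set(carriers_ol), "PO": set(carriers_po)})


class TestPresenceMatrix:
    def test_indicator_entries(self):
        regions = [_region("r1", carriers_ol={"a"}),
                   _region("r2", carriers_ol={"a", "b"}, carriers_po={"c"})]
        m = presence_matrix(regions, ["a", "b", "c"])
        np.testing.assert_array_equal(m.values, [[1, 0, 0], [1, 1, 1]])

    def test_recount_oracle_on_simulation(self, small_sim):
        from cnvpop.cnvr_builder import filter_calls, merge_calls

        calls = [c for s in small_sim.calls for c in small_sim.calls[s]]
        regions = merge_calls(filter_calls(calls), small_sim.labels)
        m = presence_matrix(regions, small_sim.config.sample_ids)
        # column sums must equal per-sample carried-region counts
        for j, s in enumerate(small_sim.config.sample_ids):
            expected = sum(s in r.carrier_set for r in regions)
            assert m.values[:, j].sum() == expected

    def test_all_zero_column_warns(self):
        with pytest.warns(UserWarning, match="ghost"):
            presence_matrix([_region("r1", carriers_ol={"a"})], ["a", "ghost"])

    def test_nonbinary_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            PresenceMatrix(["r1"], ["a", "b"], np.array([[1, 2]]))


class TestBinaryDistance:
    def test_jaccard_worked_example(self):
        # X carries {r1,r2}, Y carries {r1,r2,r3}: 1 - 2/3 = 1/3
        X = np.array([[1, 1], [1, 1], [0, 1], [0, 0]])
        d = binary_distance(X, "jaccard")
        assert d[0, 1] == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_columns_distance_zero(self):
        X = np.array([[1, 1], [0, 0], [1, 1]])
        assert binary_distance(X)[0, 1] == 0.0

    def test_disjoint_columns_distance_one(self):
        X = np.array([[1, 0], [0, 1]])
        assert binary_distance(X)[0, 1] == 1.0

    def test_two_empty_columns_distance_zero(self):
        X = np.array([[0, 0], [0, 0]])
        assert binary_distance(X)[0, 1] == 0.0

    def test_symmetry_zero_diagonal(self):
        rng = np.random.default_rng(4)
        X = rng.integers(0, 2, size=(50, 8))
        d = binary_distance(X)
        np.testing.assert_array_equal(d, d.T)
        assert (np.diag(d) == 0).all()

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError, match="metric"):
            binary_distance(np.eye(3), "manhattan")


class TestUpgma:
    def test_three_leaf_hand_example(self):
        # d(X,Y)=1/3, d(X,Z)=0.9, d(Y,Z)=0.85:
        # merge {X,Y} at 1/3, then root at (0.9+0.85)/2 = 0.875
        d = np.array([[0.0, 1 / 3, 0.9],
                      [1 / 3, 0.0, 0.85],
                      [0.9, 0.85, 0.0]])
        root = upgma(d, ["X", "Y", "Z"])
        assert root.height == pytest.approx(0.875, abs=1e-12)
        inner = [e for e in tree_edges(root) if e is not root]
        assert len(inner) == 1
        assert inner[0].members == frozenset({"X", "Y"})
        assert inner[0].height == pytest.approx(1 / 3, abs=1e-12)

    def test_two_leaves(self):
        root = upgma(np.array([[0.0, 0.4], [0.4, 0.0]]), ["a", "b"])
        assert root.height == 0.4 and root.members == frozenset({"a", "b"})

    def test_heights_monotone_along_every_path(self):
        rng = np.random.default_rng(6)
        X = rng.integers(0, 2, size=(80, 10))
        root = upgma(binary_distance(X), [f"s{i}" for i in range(10)])

        def walk(node):
            for ch in node.children:
                assert ch.height <= node.height + 1e-12
                walk(ch)

        walk(root)

    def test_tie_break_is_deterministic_under_relabelling(self):
        # four equidistant leaves: many exact ties; smallest-id pair first
        d = np.ones((4, 4)) - np.eye(4)
        root = upgma(d, ["d", "b", "c", "a"])
        first = min(tree_edges(root), key=lambda e: len(e.members))
        assert first.members == frozenset({"a", "b"})

    def test_matches_scipy_average_linkage_heights(self):
        # on tie-free matrices the merge heights must match scipy exactly
        rng = np.random.default_rng(13)
        for _ in range(10):
            n = 8
            cond = rng.uniform(0.1, 1.0, size=n * (n - 1) // 2)
            if len(np.unique(cond)) < len(cond):
                continue
            d = squareform(cond)
            root = upgma(d, [f"s{i}" for i in range(n)])
            ours = sorted(e.height for e in tree_edges(root))
            ref = sorted(average(cond)[:, 2].tolist())
            np.testing.assert_allclose(ours, ref, rtol=1e-10)


def _two_block_matrix(n_regions=60, n_samples=10, flip=0.0, seed=0):
    """Block-structured carriage: first half of samples carry the first half
    of regions, second half the rest, with optional random flips."""
    rng = np.random.default_rng(seed)
    X = np.zeros((n_regions, n_samples), dtype=np.uint8)
    X[: n_regions // 2, : n_samples // 2] = 1
    X[n_regions // 2:, n_samples // 2:] = 1
    if flip:
        mask = rng.random(X.shape) < flip
        X = np.where(mask, 1 - X, X)
    return PresenceMatrix([f"r{i}" for i in range(n_regions)],
                          [f"s{j:02d}" for j in range(n_samples)], X)


class TestMultiscaleBootstrap:
    def test_same_seed_identical_results(self):
        m = _two_block_matrix(flip=0.15, seed=2)
        t1 = multiscale_bootstrap(m, nboot=50, seed=11)
        t2 = multiscale_bootstrap(m, nboot=50, seed=11)
        e1, e2 = edge_table(t1), edge_table(t2)
        assert e1.equals(e2)
        assert to_newick(t1) == to_newick(t2)

    def test_root_support_is_one(self):
        m = _two_block_matrix(flip=0.1, seed=3)
        root = multiscale_bootstrap(m, nboot=30, seed=1)
        assert root.au == 1.0 and root.bp == 1.0

    def test_single_scale_reduces_to_counted_bp(self):
        # r_grid={1.0}: the two-parameter fit cannot run, so every edge falls
        # back to the clamped counted bootstrap probability at r=1
        m = _two_block_matrix(flip=0.2, seed=4)
        root = multiscale_bootstrap(m, r_grid=[1.0], nboot=40, seed=5)
        for e in tree_edges(root):
            if e is root:
                continue
            assert e.degenerate_fit
            assert e.au == e.bp
            assert 1 / 80 <= e.au <= 1 - 1 / 80

    def test_saturated_edge_supports_near_one(self):
        # perfectly separated blocks: the two block clusters appear in every
        # bootstrap tree, and their support must be ~1, not ~0.5
        m = _two_block_matrix(flip=0.0)
        root = multiscale_bootstrap(m, nboot=100, seed=6)
        blocks = [frozenset(f"s{j:02d}" for j in range(5)),
                  frozenset(f"s{j:02d}" for j in range(5, 10))]
        for e in tree_edges(root):
            if e.members in blocks:
                assert e.au > 0.99 and e.bp > 0.99

    def test_noisy_blocks_recovered_with_high_support(self):
        m = _two_block_matrix(n_regions=120, flip=0.1, seed=7)
        root = multiscale_bootstrap(m, nboot=200, seed=8)
        blocks = [frozenset(f"s{j:02d}" for j in range(5)),
                  frozenset(f"s{j:02d}" for j in range(5, 10))]
        found = {e.members: e for e in tree_edges(root)}
        for b in blocks:
            assert b in found
            assert found[b].au > 0.9

    def test_au_bp_in_unit_interval(self):
        m = _two_block_matrix(flip=0.25, seed=9)
        root = multiscale_bootstrap(m, nboot=60, seed=10)
        for e in tree_edges(root):
            assert 0.0 <= e.au <= 1.0 and 0.0 <= e.bp <= 1.0

    def test_too_few_samples_rejected(self):
        m = PresenceMatrix(["r1", "r2"], ["a", "b"], np.array([[1, 0], [0, 1]]))
        with pytest.raises(ValueError, match="samples"):
            multiscale_bootstrap(m, nboot=10, seed=0)


class TestNewick:
    def test_leaf_set_and_labels(self):
        m = _two_block_matrix(flip=0.1, seed=1)
        root = multiscale_bootstrap(m, nboot=30, seed=2)
        nwk = to_newick(root)
        assert nwk.endswith(";")
        for s in m.sample_ids:
            assert s in nwk
        assert "au=" in nwk and "bp=" in nwk
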