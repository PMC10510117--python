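"""Presence/absence clustering of samples with multiscale-bootstrap support.

Samples are clustered by UPGMA (size-weighted average linkage) on a binary
CNVR-carriage matrix.  Cluster support follows the multiscale bootstrap:
rows (regions) are resampled with replacement at several scale factors r of
the original row count, the fraction of resampled trees containing each
observed cluster (as a member set) gives per-scale bootstrap probabilities
BP_r, and the probit-transformed curve z_r = v*sqrt(r) + c/sqrt(r) with
z_r = Phi^-1(1 - BP_r) is fitted by weighted least squares.  The
approximately unbiased support is au = 1 - Phi(v - c) and the bias-corrected
bootstrap probability bp = 1 - Phi(v + c).  Edges whose BP is saturated at 0
or 1 on all but at most one scale cannot support the two-parameter fit; they
fall back to the clamped counted BP at the scale nearest 1 and carry a
degenerate-fit flag.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

DEFAULT_R_GRID = tuple(round(0.5 + 0.1 * i, 1) for i in range(10))  # 0.5 .. 1.4


@dataclass
class PresenceMatrix:
    region_ids: list
    sample_ids: list
    values: np.ndarray  # (n_regions, n_samples), entries in {0, 1}

    def __post_init__(self):
        self.values = np.asarray(self.values)
        if self.values.shape != (len(self.region_ids), len(self.sample_ids)):
            raise ValueError("values shape does not match ids")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("presence matrix entries must be 0 or 1")
        self.values = self.values.astype(np.uint8)

    def to_dataframe(self):
        import pandas as pd
        return pd.DataFrame(self.values, index=self.region_ids, columns=self.sample_ids)


@dataclass
class DendrogramNode:
    """A cluster in the UPGMA tree; leaves have empty children."""

    members: frozenset
    height: float
    children: tuple = ()
    au: float = math.nan
    bp: float = math.nan
    fit_v: float = math.nan
    fit_c: float = math.nan
    degenerate_fit: bool = False

    @property
    def is_leaf(self) -> bool:
        return not self.children


def presence_matrix(regions: Sequence, samples: Sequence[str]) -> PresenceMatrix:
    """0/1 carriage indicator of merged regions (rows, genome-ordered as
    given) per sample (columns).  Samples carrying nothing get a zero column
    with a warning."""
    import warnings

    sample_index = {s: j for j, s in enumerate(samples)}
    values = np.zeros((len(regions), len(samples)), dtype=np.uint8)
    seen: set = set()
    for i, r in enumerate(regions):
        for s in r.carrier_set:
            j = sample_index.get(s)
            if j is not None:
                values[i, j] = 1
                seen.add(s)
    missing = [s for s in samples if s not in seen]
    if missing and len(regions):
        warnings.warn(f"samples carrying no region (all-zero columns): {missing}")
    return PresenceMatrix(
        region_ids=[r.region_id for r in regions],
        sample_ids=list(samples), values=values)


def binary_distance(matrix, metric: str = "jaccard") -> np.ndarray:
    """Pairwise sample distances over region rows.

    jaccard: 1 - |intersection| / |union| of carried regions (0 for two
    all-zero samples); euclidean: on raw 0/1 columns; correlation:
    1 - Pearson r between columns (constant columns treated as uncorrelated).
    """
    X = matrix.values if isinstance(matrix, PresenceMatrix) else np.asarray(matrix)
    X = X.astype(float)
    if X.shape[1] < 2:
        raise ValueError("need >= 2 samples")
    if metric == "jaccard":
        inter = X.T @ X
        counts = X.sum(axis=0)
        union = counts[:, None] + counts[None, :] - inter
        with np.errstate(invalid="ignore", divide="ignore"):
            d = 1.0 - np.where(union > 0, inter / np.where(union > 0, union, 1.0), 1.0)
        d[union == 0] = 0.0
    elif metric == "euclidean":
        diff = X[:, :, None] - X[:, None, :]
        d = np.sqrt((diff ** 2).sum(axis=0))
    elif metric == "correlation":
        Xc = X - X.mean(axis=0)
        sd = np.sqrt((Xc ** 2).sum(axis=0))
        denom = sd[:, None] * sd[None, :]
        with np.errstate(invalid="ignore", divide="ignore"):
            corr = np.where(denom > 0, (Xc.T @ Xc) / np.where(denom > 0, denom, 1.0), 0.0)
        d = 1.0 - corr
    else:
        raise ValueError(f"unknown metric {metric!r}")
    np.fill_diagonal(d, 0.0)
    return (d + d.T) / 2.0  # enforce exact symmetry against rounding


def upgma(dist: np.ndarray, labels: Sequence[str]) -> DendrogramNode:
    """Size-weighted average-linkage agglomeration into an ultrametric tree.

    Ties between equally close pairs are broken by the lexicographically
    smallest (min member id, min member id) pair, which makes the tree
    deterministic on 0/1 data where exact ties are common.
    """
    dist = np.asarray(dist, dtype=float)
    n = len(labels)
    if dist.shape != (n, n):
        raise ValueError("distance matrix shape does not match labels")
    if not np.allclose(dist, dist.T, atol=1e-12):
        raise ValueError("distance matrix must be symmetric")
    D = dist.copy()
    nodes = [DendrogramNode(members=frozenset([l]), height=0.0) for l in labels]
    sizes = [1] * n
    min_ids = [str(l) for l in labels]
    active = list(range(n))

    while len(active) > 1:
        idx = np.asarray(active)
        sub = D[np.ix_(idx, idx)].copy()
        iu = np.triu_indices(len(idx), k=1)
        vals = sub[iu]
        m = vals.min()
        ties = np.nonzero(vals == m)[0]
        if len(ties) == 1:
            t = ties[0]
        else:
            t = min(ties, key=lambda tt: tuple(sorted(
                (min_ids[idx[iu[0][tt]]], min_ids[idx[iu[1][tt]]]))))
        a, b = int(idx[iu[0][t]]), int(idx[iu[1][t]])
        h = D[a, b]
        merged = DendrogramNode(
            members=nodes[a].members | nodes[b].members,
            height=h, children=(nodes[a], nodes[b]))
        # size-weighted average distance from the merged cluster to the rest
        for c in active:
            if c in (a, b):
                continue
            D[a, c] = D[c, a] = (sizes[a] * D[a, c] + sizes[b] * D[b, c]) / (sizes[a] + sizes[b])
        nodes[a] = merged
        sizes[a] += sizes[b]
        min_ids[a] = min(min_ids[a], min_ids[b])
        active.remove(b)
    return nodes[active[0]]


def tree_edges(root: DendrogramNode) -> list[DendrogramNode]:
    """Internal nodes (clusters of >= 2 members), root last."""
    out: list[DendrogramNode] = []

    def walk(node):
        if node.is_leaf:
            return
        for ch in node.children:
            walk(ch)
        out.append(node)

    walk(root)
    return out


def _edge_sets(root: DendrogramNode) -> set:
    return {e.members for e in tree_edges(root)}


def _fit_edge(counts: np.ndarray, r_grid: np.ndarray, nboot: int,
              r1_index: int) -> tuple:
    """Fit the probit-scale curve for one edge.

    Returns (au, bp, v, c, degenerate).  Scales where the counted BP is
    exactly 0 or 1 carry no curvature information; if fewer than two scales
    are informative the fit is degenerate and au falls back to the clamped
    counted BP at the scale closest to r = 1.
    """
    clamp = 1.0 / (2.0 * nboot)
    bp_r = counts / nboot
    usable = (counts > 0) & (counts < nboot)
    if usable.sum() < 2:
        val = float(np.clip(bp_r[r1_index], clamp, 1.0 - clamp))
        return val, val, math.nan, math.nan, True
    bpc = np.clip(bp_r, clamp, 1.0 - clamp)
    z = stats.norm.isf(bpc)  # Phi^-1(1 - BP_r)
    # inverse-variance weights via the delta method on the probit transform
    w = nboot * stats.norm.pdf(z) ** 2 / (bpc * (1.0 - bpc))
    X = np.column_stack([np.sqrt(r_grid), 1.0 / np.sqrt(r_grid)])
    XtW = X.T * w
    v, c = np.linalg.solve(XtW @ X, XtW @ z)
    au = float(stats.norm.sf(v - c))
    bp = float(stats.norm.sf(v + c))
    return au, bp, float(v), float(c), False


def multiscale_bootstrap(
    matrix: PresenceMatrix,
    r_grid: Sequence[float] = DEFAULT_R_GRID,
    nboot: int = 1000,
    metric: str = "jaccard",
    seed: int | None = None,
) -> DendrogramNode:
    """Cluster samples by UPGMA and attach AU/BP support to every cluster.

    Rows (regions) are the resampling unit; columns (samples) are clustered.
    Deterministic given the seed.  The root (all samples) has support 1 by
    convention.
    """
    X = matrix.values
    n_rows, n_samples = X.shape
    if n_samples < 3 or n_rows < 2:
        raise ValueError("need >= 3 samples and >= 2 regions")
    r_grid = np.asarray(sorted(float(r) for r in r_grid))
    if len(r_grid) < 1:
        raise ValueError("empty r_grid")
    rng = np.random.default_rng(seed)

    root = upgma(binary_distance(X, metric), matrix.sample_ids)
    edges = tree_edges(root)
    observed = {e.members: np.zeros(len(r_grid)) for e in edges}

    for ri, r in enumerate(r_grid):
        n_r = max(2, round(r * n_rows))
        for _ in range(nboot):
            idx = rng.integers(0, n_rows, size=n_r)
            boot_root = upgma(binary_distance(X[idx], metric), matrix.sample_ids)
            for members in _edge_sets(boot_root):
                hits = observed.get(members)
                if hits is not None:
                    hits[ri] += 1

    r1_index = int(np.argmin(np.abs(r_grid - 1.0)))
    for e in edges:
        if len(e.members) == n_samples:  # trivial all-samples cluster
            e.au = e.bp = 1.0
            continue
        e.au, e.bp, e.fit_v, e.fit_c, e.degenerate_fit = _fit_edge(
            observed[e.members], r_grid, nboot, r1_index)
    return root


def edge_table(root: DendrogramNode):
    """Flat per-cluster table of heights and support values."""
    import pandas as pd
    rows = [
        {
            "members": ",".join(sorted(e.members)),
            "n_members": len(e.members),
            "height": e.height,
            "au": e.au,
            "bp": e.bp,
            "fit_v": e.fit_v,
            "fit_c": e.fit_c,
            "degenerate_fit": e.degenerate_fit,
        }
        for e in tree_edges(root)
    ]
    return pd.DataFrame(rows)


def to_newick(root: DendrogramNode) -> str:
    """Newick serialization with au/bp as quoted internal-node labels and
    ultrametric branch lengths."""

    def fmt(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            (leaf,) = node.members
            return f"{leaf}:{length:.6g}"
        inner = ",".join(fmt(ch, node.height) for ch in node.children)
        label = f"'au={node.au:.3f}|bp={node.bp:.3f}'"
        return f"({inner}){label}:{length:.6g}"

    return fmt(root, root.height) + ";"
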