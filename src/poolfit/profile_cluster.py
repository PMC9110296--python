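"""Phenotype-profile normalization and hierarchical clustering.

Gene profiles are the log2 median phenotypes across screens, median-centered
per screen so that the typical gene sits at zero in every screen. Genes are
clustered by UPGMA (average linkage) on the Pearson correlation distance
d = 1 - r computed over pairwise-complete screens; GO x screen enrichment
matrices use Euclidean distance instead. The linkage is computed by an
in-package UPGMA with a deterministic smallest-leaf tie-break so results are
reproducible bit-for-bit across runs and input orderings.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd


@dataclass
class LinkageResult:
    """Agglomeration record: ``merges`` lists (node_a, node_b, distance,
    size) with leaves 0..n-1 and internal node i created by merge i-n;
    ``leaf_order`` is the dendrogram's left-to-right leaf sequence."""

    merges: list[tuple[int, int, float, int]]
    leaf_order: list[int]
    labels: list[str] | None = None

    @property
    def n_leaves(self) -> int:
        return len(self.merges) + 1

    def to_linkage_matrix(self) -> np.ndarray:
        """Linkage in the conventional (n-1) x 4 matrix layout."""
        return np.array([[a, b, d, s] for a, b, d, s in self.merges], dtype=float)


def median_center(matrix: pd.DataFrame) -> pd.DataFrame:
    """Subtract each screen's (column's) median over non-missing entries.

    Idempotent; all-missing columns are left as-is with a warning.
    """
    out = matrix.copy().astype(float)
    for col in out.columns:
        vals = out[col]
        if vals.isna().all():
            warnings.warn(f"column {col!r} is all-missing; left uncentered")
            continue
        out[col] = vals - vals.median()
    return out


def correlation_distance(x, y) -> float:
    """Pearson correlation distance 1 - r over pairwise-complete positions.

    Zero-variance profiles (over the overlap) get distance 1 — r is treated
    as 0 because a flat profile carries no co-variation signal.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    mask = ~(np.isnan(x) | np.isnan(y))
    if mask.sum() < 2:
        raise ValueError("need >= 2 overlapping non-missing positions")
    xs, ys = x[mask], y[mask]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    vx, vy = (xs ** 2).sum(), (ys ** 2).sum()
    if vx == 0 or vy == 0:
        warnings.warn("zero-variance profile; correlation distance set to 1")
        return 1.0
    return float(1.0 - (xs * ys).sum() / np.sqrt(vx * vy))


def condensed_distances(matrix: pd.DataFrame, metric: str = "correlation") -> np.ndarray:
    """Condensed pairwise distance vector over the matrix rows."""
    n = len(matrix)
    vals = matrix.to_numpy(dtype=float)
    out = []
    for i in range(n):
        for j in range(i + 1, n):
            if metric == "correlation":
                out.append(correlation_distance(vals[i], vals[j]))
            elif metric == "euclidean":
                out.append(float(np.sqrt(np.nansum((vals[i] - vals[j]) ** 2))))
            else:
                raise ValueError(f"unknown metric {metric!r}")
    return np.asarray(out)


def average_linkage(dist, labels: list[str] | None = None) -> LinkageResult:
    """UPGMA agglomeration of a condensed distance vector.

    Inter-cluster distance is the unweighted mean of all cross-pair leaf
    distances; equal-distance candidate pairs are broken by the smallest
    (then second-smallest) leaf index among cluster representatives, so the
    merge sequence is deterministic and independent of input row order.
    """
    dist = np.asarray(dist, dtype=float)
    m = dist.size
    n = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if n < 2 or n * (n - 1) // 2 != m:
        raise ValueError("not a valid condensed distance vector (need >= 2 leaves)")

    full = np.zeros((n, n))
    idx = np.triu_indices(n, 1)
    full[idx] = dist
    full += full.T

    # active clusters, keyed by their smallest member leaf; cross-cluster
    # distances maintained by the unweighted-average Lance-Williams update
    size = {i: 1 for i in range(n)}
    node_of = {i: i for i in range(n)}
    active = set(range(n))
    D = {frozenset((i, j)): full[i, j] for i in range(n) for j in range(i + 1, n)}
    merges: list[tuple[int, int, float, int]] = []
    next_node = n
    trees: dict[int, object] = {i: i for i in range(n)}

    while len(active) > 1:
        keys = sorted(active)
        best = None  # (distance, repr_a, repr_b)
        for ai in range(len(keys)):
            for bi in range(ai + 1, len(keys)):
                a, b = keys[ai], keys[bi]
                cand = (D[frozenset((a, b))], a, b)
                if best is None or cand < best:
                    best = cand
        d, a, b = best  # a < b: keys are each cluster's smallest leaf
        na, nb = node_of[a], node_of[b]
        if na > nb:
            na, nb = nb, na
        merges.append((na, nb, float(d), size[a] + size[b]))
        trees[next_node] = (trees[na], trees[nb])
        for c in active - {a, b}:
            D[frozenset((a, c))] = (
                size[a] * D[frozenset((a, c))] + size[b] * D[frozenset((b, c))]
            ) / (size[a] + size[b])
        size[a] += size[b]
        node_of[a] = next_node
        active.remove(b)
        next_node += 1

    def leaves(t) -> list[int]:
        if isinstance(t, int):
            return [t]
        return leaves(t[0]) + leaves(t[1])

    return LinkageResult(merges=merges, leaf_order=leaves(trees[next_node - 1]), labels=labels)


def pearson_matrix(
    matrix_a: pd.DataFrame, matrix_b: pd.DataFrame | None = None, min_periods: int = 2
) -> pd.DataFrame:
    """Gene x gene pairwise-complete Pearson correlation matrix.

    With one input, correlates its rows with each other (diagonal = 1);
    with two, correlates rows of ``matrix_a`` against rows of ``matrix_b``
    over their shared columns (e.g. phenotype vs expression profiles).
    """
    a = matrix_a.T  # pandas corr works column-wise
    if matrix_b is None:
        return a.corr(min_periods=min_periods)
    shared = matrix_a.columns.intersection(matrix_b.columns)
    if len(shared) < min_periods:
        raise ValueError("matrices share too few columns")
    va = matrix_a[shared].to_numpy(dtype=float)
    vb = matrix_b[shared].to_numpy(dtype=float)
    out = pd.DataFrame(np.nan, index=matrix_a.index, columns=matrix_b.index, dtype=float)
    for i in range(va.shape[0]):
        for j in range(vb.shape[0]):
            mask = ~(np.isnan(va[i]) | np.isnan(vb[j]))
            if mask.sum() < min_periods:
                continue
            x, y = va[i, mask], vb[j, mask]
            if x.std() == 0 or y.std() == 0:
                continue
            out.iloc[i, j] = float(np.corrcoef(x, y)[0, 1])
    return out


def cluster_profiles(matrix: pd.DataFrame, metric: str = "correlation") -> LinkageResult:
    """Median-centered profile clustering: distance + average linkage."""
    return average_linkage(condensed_distances(matrix, metric), labels=list(matrix.index))


def cluster_go_matrix(enrichment: pd.DataFrame, floor: float = 1e-300) -> LinkageResult:
    """Cluster a GO x screen FDR matrix: -log10(FDR floored at 1e-300),
    Euclidean distance, average linkage."""
    vals = -np.log10(enrichment.clip(lower=floor))
    return average_linkage(condensed_distances(vals, "euclidean"), labels=list(enrichment.index))


def to_newick(result: LinkageResult) -> str:
    """Newick serialization of the dendrogram (branch lengths from merge
    heights)."""
    labels = result.labels or [str(i) for i in range(result.n_leaves)]
    height = {i: 0.0 for i in range(result.n_leaves)}
    node_str = {i: labels[i] for i in range(result.n_leaves)}
    nid = result.n_leaves
    for a, b, d, _ in result.merges:
        la = d - height[a]
        lb = d - height[b]
        node_str[nid] = f"({node_str[a]}:{la:.6g},{node_str[b]}:{lb:.6g})"
        height[nid] = d
        nid += 1
    return node_str[nid - 1] + ";"
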