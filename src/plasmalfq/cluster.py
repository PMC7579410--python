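"""Temporal-profile clustering with seriation.

Population-responsive proteins are grouped by the similarity of their mean
abundance profile across sampling days: rows are z-scored (display parity
only — Pearson correlation is affine-invariant), dissimilarity is
d = 1 - Pearson r, trees use complete linkage, and leaves are ordered by
seriation.  The returned seriation is the order consistent with the
dendrogram (branch flips) minimising the sum of adjacent-leaf
dissimilarities; the unconstrained multiple-fragment greedy path is exposed
separately as a diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

__all__ = [
    "LinkageTree",
    "zscore_rows",
    "corr_dissimilarity",
    "hclust_complete",
    "mf_path",
    "mf_seriation",
    "cut_clusters",
    "path_length",
    "to_newick",
]


@dataclass
class LinkageTree:
    """A hierarchical clustering result: scipy linkage matrix plus labels."""

    linkage: np.ndarray
    labels: list[str]

    def __post_init__(self) -> None:
        if self.linkage.shape != (len(self.labels) - 1, 4):
            raise ValueError("linkage shape inconsistent with label count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights must be non-decreasing")


def zscore_rows(profile: pd.DataFrame) -> pd.DataFrame:
    """Centre each row to mean 0 and scale to SD 1 (denominator n-1)."""
    sd = profile.std(axis=1, ddof=1)
    flat = sd[sd == 0]
    if len(flat):
        raise ValueError(f"constant row(s): {list(flat.index)}")
    return profile.sub(profile.mean(axis=1), axis=0).div(sd, axis=0)


def corr_dissimilarity(profile: pd.DataFrame) -> np.ndarray:
    """Pairwise d(i, j) = 1 - Pearson r between rows; range [0, 2]."""
    if len(profile) < 2:
        raise ValueError("need at least two rows")
    if (profile.std(axis=1, ddof=1) == 0).any():
        raise ValueError("constant row has undefined correlation")
    d = 1.0 - np.corrcoef(profile.to_numpy())
    np.fill_diagonal(d, 0.0)
    return np.clip((d + d.T) / 2.0, 0.0, 2.0)


def _check_dissimilarity(d: np.ndarray) -> np.ndarray:
    d = np.asarray(d, float)
    if np.isnan(d).any():
        raise ValueError("NaN in dissimilarity matrix")
    if d.ndim != 2 or d.shape[0] != d.shape[1]:
        raise ValueError("dissimilarity must be square")
    if not np.allclose(d, d.T) or not np.allclose(np.diag(d), 0) or (d < 0).any():
        raise ValueError("dissimilarity must be symmetric, non-negative, zero-diagonal")
    return d


def hclust_complete(
    dissimilarity: np.ndarray, labels: Sequence[str] | None = None
) -> LinkageTree:
    """Agglomerative complete-linkage (furthest-neighbour) clustering."""
    d = _check_dissimilarity(dissimilarity)
    if labels is None:
        labels = [str(i) for i in range(d.shape[0])]
    z = hierarchy.linkage(squareform(d, checks=False), method="complete")
    return LinkageTree(linkage=z, labels=list(labels))


def path_length(d: np.ndarray, order: Sequence[int]) -> float:
    """Sum of dissimilarities between adjacent items of an order."""
    order = list(order)
    return float(sum(d[order[i], order[i + 1]] for i in range(len(order) - 1)))


def mf_path(dissimilarity: np.ndarray) -> list[int]:
    """Multiple-fragment greedy path: repeatedly add the globally smallest
    edge joining two fragment endpoints without closing a cycle."""
    d = _check_dissimilarity(dissimilarity)
    n = d.shape[0]
    if n == 1:
        return [0]
    edges = sorted(
        ((d[i, j], i, j) for i in range(n) for j in range(i + 1, n)),
        key=lambda t: (t[0], t[1], t[2]),
    )
    degree = [0] * n
    fragment = list(range(n))  # union-find over path fragments
    neighbours: dict[int, list[int]] = {i: [] for i in range(n)}

    def find(i: int) -> int:
        while fragment[i] != i:
            fragment[i] = fragment[fragment[i]]
            i = fragment[i]
        return i

    added = 0
    for _, i, j in edges:
        if degree[i] >= 2 or degree[j] >= 2 or find(i) == find(j):
            continue
        fragment[find(i)] = find(j)
        degree[i] += 1
        degree[j] += 1
        neighbours[i].append(j)
        neighbours[j].append(i)
        added += 1
        if added == n - 1:
            break
    start = min(i for i in range(n) if degree[i] <= 1)
    order = [start]
    prev = None
    while len(order) < n:
        nxt = [k for k in neighbours[order[-1]] if k != prev]
        prev = order[-1]
        order.append(nxt[0])
    return order


def mf_seriation(dissimilarity: np.ndarray, tree: LinkageTree) -> list[str]:
    """Leaf order consistent with the tree (branch flips) minimising the sum
    of adjacent-leaf dissimilarities."""
    d = _check_dissimilarity(dissimilarity)
    if d.shape[0] != len(tree.labels):
        raise ValueError("tree and dissimilarity disagree on leaf count")
    z = hierarchy.optimal_leaf_ordering(tree.linkage, squareform(d, checks=False))
    return [tree.labels[i] for i in hierarchy.leaves_list(z)]


def cut_clusters(
    tree: LinkageTree,
    k: int | None = None,
    height: float | None = None,
    order: Sequence[str] | None = None,
) -> dict[str, int]:
    """Cut the tree into flat clusters by count ``k`` or merge ``height``.

    Cluster ids are renumbered 1..k by first appearance along ``order`` (the
    seriation order) when given, otherwise along the label order.
    """
    n = len(tree.labels)
    if (k is None) == (height is None):
        raise ValueError("give exactly one of k or height")
    if k is not None:
        if not 1 <= k <= n:
            raise ValueError(f"k must be in [1, {n}]")
        raw = hierarchy.fcluster(tree.linkage, k, criterion="maxclust")
    else:
        if height < 0:
            raise ValueError("height must be >= 0")
        raw = hierarchy.fcluster(tree.linkage, height, criterion="distance")
    by_label = dict(zip(tree.labels, (int(c) for c in raw)))
    walk = list(order) if order is not None else list(tree.labels)
    renumber: dict[int, int] = {}
    for lab in walk:
        c = by_label[lab]
        if c not in renumber:
            renumber[c] = len(renumber) + 1
    return {lab: renumber[c] for lab, c in by_label.items()}


def to_newick(tree: LinkageTree) -> str:
    """Newick export of the dendrogram with merge heights as branch lengths."""
    z = tree.linkage
    n = len(tree.labels)
    height = {i: 0.0 for i in range(n)}

    def node(i: int) -> str:
        if i < n:
            return tree.labels[i]
        a, b, h, _ = z[i - n]
        height[i] = h
        left, right = int(a), int(b)
        return (
            f"({node(left)}:{h - height[left]:.6g},"
            f"{node(right)}:{h - height[right]:.6g})"
        )

    return node(2 * n - 2) + ";"
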