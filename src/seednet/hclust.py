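"""Shared hierarchical-clustering helpers: dendrogram cutting, clade checks,
Newick export.

The cut rule used throughout the pipeline ("as many clusters as possible
without singletons") scans every horizontal cut of the dendrogram at the
distinct merge heights and returns the partition with the largest number
of clusters subject to every cluster holding at least two leaves; ties
are broken by the lowest qualifying cut height.
"""

from __future__ import annotations

import numpy as np
from scipy.cluster.hierarchy import cut_tree, linkage

__all__ = [
    "cut_max_no_singletons",
    "labels_to_clusters",
    "contains_clade",
    "linkage_to_newick",
]


def labels_to_clusters(labels: np.ndarray, leaf_names: list) -> list[set]:
    """Group leaf names by flat-cluster label."""
    clusters: dict[int, set] = {}
    for name, label in zip(leaf_names, np.asarray(labels).ravel()):
        clusters.setdefault(int(label), set()).add(name)
    return list(clusters.values())


def cut_max_no_singletons(Z: np.ndarray, leaf_names: list | None = None):
    """Cut a linkage matrix maximizing cluster count without singletons.

    Candidate cuts lie just below each distinct merge height (plus the
    trivial one-cluster cut above the root). Among partitions whose
    smallest cluster has >= 2 leaves, the one with the most clusters
    wins; among those, the lowest cut height. With n = 2 leaves the only
    valid partition is the single pair.

    Returns ``(clusters, cut_height)`` where clusters is a list of sets
    of leaf names (leaf indices if names are not given).
    """
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    if n < 2:
        raise ValueError("dendrogram needs at least 2 leaves")
    if leaf_names is None:
        leaf_names = list(range(n))
    heights = np.unique(Z[:, 2])
    best = None  # (n_clusters, -height) maximized
    # cutting below the smallest height gives all singletons (invalid for
    # n > 1); cutting at/above the root height gives one cluster.
    candidates = list(heights) + [heights[-1] + 1.0]
    for h in candidates:
        # clusters formed by applying all merges with height < h
        t = np.nextafter(h, -np.inf) if h in heights else h
        labels = cut_tree(Z, height=t).ravel()
        clusters = labels_to_clusters(labels, leaf_names)
        if min(len(c) for c in clusters) < 2:
            continue
        key = (len(clusters), -h)
        if best is None or key > best[0]:
            best = (key, clusters, h)
    if best is None:  # every cut isolates a leaf -> root cluster
        return [set(leaf_names)], float(heights[-1])
    return best[1], float(best[2])


def contains_clade(Z: np.ndarray, leaf_names: list, subset: set) -> bool:
    """True if ``subset`` appears as an exact clade of the dendrogram.

    A clade is the full leaf set under some internal node (or a single
    leaf).
    """
    n = Z.shape[0] + 1
    name_of = {i: {leaf_names[i]} for i in range(n)}
    subset = set(subset)
    if len(subset) == 1:
        return next(iter(subset)) in leaf_names
    for i, (a, b, _, _) in enumerate(np.asarray(Z, dtype=float).tolist()):
        members = name_of[int(a)] | name_of[int(b)]
        name_of[n + i] = members
        if members == subset:
            return True
    return False


def linkage_to_newick(Z: np.ndarray, leaf_names: list) -> str:
    """Serialize a scipy linkage matrix as a Newick string with branch lengths."""
    Z = np.asarray(Z, dtype=float)
    n = Z.shape[0] + 1
    height = {i: 0.0 for i in range(n)}
    node: dict[int, str] = {i: str(leaf_names[i]) for i in range(n)}
    for i, (a, b, h, _) in enumerate(Z.tolist()):
        a, b = int(a), int(b)
        la = h - height[a]
        lb = h - height[b]
        node[n + i] = f"({node[a]}:{la:.6g},{node[b]}:{lb:.6g})"
        height[n + i] = h
    return node[n + Z.shape[0] - 1] + ";"


def cluster_matrix(
    matrix: np.ndarray,
    metric: str = "euclidean",
    method: str = "complete",
) -> np.ndarray:
    """Row linkage of a matrix (thin wrapper kept for a single call site)."""
    return linkage(matrix, method=method, metric=metric)
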