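"""Hierarchical clustering of mixed miRNA/variable profiles.

Profiles are scaled (row z-score, or per-row median-centred log2), turned
into a Pearson distance matrix d = 1 - r, and agglomerated with unweighted
average linkage (UPGMA): at each step the closest pair of clusters merges,
and the distance between clusters is the mean of all cross-pair leaf
distances.  Ties are broken deterministically by the lexicographically
smallest leaf-id pair, so the tree is invariant to input row order.

Trees serialize to Newick; under the UPGMA ultrametric convention a node
sits at half its merge height, so a child's branch length is
(parent_height - child_height) / 2.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd


@dataclass
class ClusterNode:
    """A node of the binary merge tree.

    Leaves have ``label`` set and height 0; internal nodes carry the merge
    height and exactly two children (left child holds the lexicographically
    smaller minimal leaf id).
    """

    height: float
    label: str | None = None
    children: tuple["ClusterNode", "ClusterNode"] | None = None

    @property
    def leaves(self) -> list[str]:
        if self.children is None:
            return [self.label]
        return self.children[0].leaves + self.children[1].leaves

    @property
    def key(self) -> str:
        """Lexicographically smallest leaf id under this node (tie-break key)."""
        if self.children is None:
            return self.label
        return min(self.children[0].key, self.children[1].key)

    def to_newick(self, parent_height: float | None = None) -> str:
        if parent_height is None:
            body = self._newick_body(self.height)
            return body + ";"
        return self._newick_body(parent_height)

    def _newick_body(self, parent_height: float) -> str:
        bl = (parent_height - self.height) / 2.0
        if self.children is None:
            return f"{self.label}:{bl:.6g}"
        inner = ",".join(c._newick_body(self.height) for c in self.children)
        return f"({inner}):{bl:.6g}"


@dataclass
class ClusterTree:
    root: ClusterNode
    merges: list[tuple[str, str, float]]  # (left key, right key, height)

    @property
    def leaf_order(self) -> list[str]:
        return self.root.leaves

    def to_newick(self) -> str:
        return self.root.to_newick()


def scale_features(matrix: pd.DataFrame, mode: str = "zscore", pseudocount: float = 0.0) -> pd.DataFrame:
    """Row-wise scaling.

    ``zscore``: mean-centre then divide by the sample standard deviation of
    each row; constant rows are dropped with a warning.  ``median_log2``:
    log2-transform (after adding ``pseudocount``) then subtract each row's
    median log2 value.
    """
    if mode == "zscore":
        vals = matrix.to_numpy(dtype=float)
        sd = vals.std(axis=1, ddof=1)
        constant = sd == 0
        if constant.any():
            dropped = list(matrix.index[constant])
            warnings.warn(f"dropping constant rows: {dropped}", stacklevel=2)
        keep = matrix.loc[~constant]
        vals = keep.to_numpy(dtype=float)
        scaled = (vals - vals.mean(axis=1, keepdims=True)) / vals.std(axis=1, ddof=1, keepdims=True)
        return pd.DataFrame(scaled, index=keep.index, columns=keep.columns)
    if mode == "median_log2":
        vals = matrix.to_numpy(dtype=float) + pseudocount
        if (vals <= 0).any():
            raise ValueError("median_log2 requires positive values (set a pseudocount)")
        logv = np.log2(vals)
        scaled = logv - np.median(logv, axis=1, keepdims=True)
        return pd.DataFrame(scaled, index=matrix.index, columns=matrix.columns)
    raise ValueError(f"unknown scaling mode {mode!r}")


def pearson_distance(matrix: pd.DataFrame) -> pd.DataFrame:
    """Pairwise distance d(i, j) = 1 - r(i, j) between rows; range [0, 2]."""
    vals = matrix.to_numpy(dtype=float)
    if (vals.std(axis=1) == 0).any():
        bad = list(matrix.index[vals.std(axis=1) == 0])
        raise ValueError(f"constant rows have undefined correlation: {bad}")
    r = np.corrcoef(vals)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip(d, 0.0, 2.0)
    return pd.DataFrame(d, index=matrix.index, columns=matrix.index)


def average_linkage(distances: pd.DataFrame) -> ClusterTree:
    """UPGMA agglomeration of a symmetric distance matrix.

    Inter-cluster distance is the unweighted mean over all cross-pair leaf
    distances (Lance-Williams size-weighted update); tied candidate pairs
    are resolved by the smallest (lexicographic) pair of cluster keys.
    """
    n = distances.shape[0]
    if n < 2:
        raise ValueError("need at least 2 items to cluster")
    if list(distances.index) != list(distances.columns):
        raise ValueError("distance matrix index and columns must match")
    dvals = distances.to_numpy(dtype=float)
    if not np.allclose(dvals, dvals.T, atol=1e-10):
        raise ValueError("distance matrix must be symmetric")

    labels = [str(x) for x in distances.index]
    clusters: dict[int, ClusterNode] = {
        i: ClusterNode(height=0.0, label=lab) for i, lab in enumerate(labels)
    }
    sizes = {i: 1 for i in range(n)}
    dist = {
        (i, j): float(dvals[i, j]) for i in range(n) for j in range(i + 1, n)
    }
    merges: list[tuple[str, str, float]] = []
    next_id = n
    while len(clusters) > 1:
        # Closest pair; ties resolved on the sorted (key_a, key_b) pair.
        best = min(
            dist.items(),
            key=lambda kv: (
                kv[1],
                tuple(sorted((clusters[kv[0][0]].key, clusters[kv[0][1]].key))),
            ),
        )
        (i, j), h = best
        a, b = clusters.pop(i), clusters.pop(j)
        left, right = (a, b) if a.key <= b.key else (b, a)
        node = ClusterNode(height=h, children=(left, right))
        merges.append((left.key, right.key, h))
        na, nb = sizes.pop(i), sizes.pop(j)
        for k in list(clusters):
            dik = dist.pop((min(i, k), max(i, k)))
            djk = dist.pop((min(j, k), max(j, k)))
            dist[(min(next_id, k), max(next_id, k))] = (na * dik + nb * djk) / (na + nb)
        del dist[(i, j)]
        clusters[next_id] = node
        sizes[next_id] = na + nb
        next_id += 1
    return ClusterTree(root=next(iter(clusters.values())), merges=merges)


def cluster_profiles(matrix: pd.DataFrame, scale_mode: str = "zscore") -> ClusterTree:
    """Scale rows, build the Pearson distance matrix, and cluster."""
    scaled = scale_features(matrix, mode=scale_mode)
    return average_linkage(pearson_distance(scaled))


def tissue_enrichment(
    tissue_matrix: pd.DataFrame,
    brain_reference_column: str = "brain",
    pseudocount: float = 0.5,
) -> tuple[pd.DataFrame, ClusterTree, pd.Series]:
    """Tissue-panel variant: total-normalize columns, median-centre log2
    rows, cluster miRNAs, and flag brain enrichment.

    A miRNA is flagged brain-enriched when its normalized level in the
    reference column strictly exceeds the 75th percentile of its levels
    across all tissues.
    """
    if brain_reference_column not in tissue_matrix.columns:
        raise ValueError(f"missing reference column {brain_reference_column!r}")
    shifted = tissue_matrix + pseudocount  # keeps zero counts loggable
    norm = shifted / shifted.sum(axis=0)
    scaled = scale_features(norm, mode="median_log2")
    tree = average_linkage(pearson_distance(scaled))
    q75 = norm.quantile(0.75, axis=1)
    flags = norm[brain_reference_column] > q75
    flags.name = "brain_enriched"
    return scaled, tree, flags
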