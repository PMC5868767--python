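"""Bit-score distance clustering of protein families.

All-vs-all local alignments give normalised bit scores S(i, j); the
dissimilarity between two proteins is

    d(i, j) = 1 - S(i, j) / min(S(i, i), S(j, j)),

clipped to [0, 1] — zero for identical sequences, near one for unrelated
ones, monotone in the bit score. Ward agglomerative clustering on this
matrix groups family members; the quality of the tree is summarised by the
cophenetic correlation (and, secondarily, the agglomerative coefficient),
and the dendrogram exports to Newick for standard tree viewers.

Hierarchical clustering itself is delegated to scipy.cluster.hierarchy.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .alignment import AlnParams, bit_score, local_score
from .sequence import ProteinRecord


@dataclass
class DistanceMatrix:
    """Symmetric dissimilarity matrix with zero diagonal."""

    ids: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.ids)
        if self.d.shape != (n, n):
            raise ValueError(f"matrix shape {self.d.shape} does not match {n} ids")
        if not np.allclose(self.d, self.d.T):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(self.d), 0.0):
            raise ValueError("distance matrix diagonal is not zero")
        if not np.all(np.isfinite(self.d)):
            raise ValueError("distance matrix has non-finite entries")

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(self.d, index=self.ids, columns=self.ids)


@dataclass
class Dendrogram:
    """A scipy-format linkage with leaf labels (method recorded)."""

    leaf_ids: list[str]
    linkage: np.ndarray
    method: str = "ward"

    def __post_init__(self) -> None:
        n = len(self.leaf_ids)
        if self.linkage.shape != (n - 1, 4):
            raise ValueError("linkage shape does not match leaf count")
        heights = self.linkage[:, 2]
        if np.any(np.diff(heights) < -1e-9):
            raise ValueError("merge heights are not monotone non-decreasing")

    def cut(self, n_clusters: int) -> dict[str, int]:
        """Leaf id -> cluster label (1..n_clusters)."""
        labels = hierarchy.fcluster(self.linkage, n_clusters, criterion="maxclust")
        return dict(zip(self.leaf_ids, (int(x) for x in labels)))


def bitscore_distance_matrix(
    records: Sequence[ProteinRecord], params: AlnParams | None = None
) -> DistanceMatrix:
    """All-vs-all local-alignment bit-score distances (see module docs)."""
    params = params or AlnParams.blast_default()
    n = len(records)
    if n < 2:
        raise ValueError("need at least two sequences")
    self_bits = np.empty(n)
    for i, r in enumerate(records):
        s = bit_score(local_score(r.seq, r.seq, params), params)
        if s <= 0:
            raise ValueError(f"non-positive self bit score for {r.id!r}")
        self_bits[i] = s
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            bits = bit_score(
                local_score(records[i].seq, records[j].seq, params), params
            )
            val = 1.0 - bits / min(self_bits[i], self_bits[j])
            d[i, j] = d[j, i] = min(1.0, max(0.0, val))
    return DistanceMatrix([r.id for r in records], d)


def ward_cluster(dist: DistanceMatrix) -> Dendrogram:
    """Ward agglomerative clustering (Lance–Williams recursion via scipy)."""
    condensed = squareform(dist.d, checks=True)
    link = hierarchy.linkage(condensed, method="ward")
    return Dendrogram(list(dist.ids), link, "ward")


@dataclass
class ClusteringQuality:
    """Both published interpretations of a clustering quality coefficient."""

    cophenetic_correlation: float
    agglomerative_coefficient: float


def clustering_coefficient(
    dist: DistanceMatrix, dendrogram: Dendrogram
) -> ClusteringQuality:
    """Quality of a hierarchical clustering against its input distances.

    The cophenetic correlation is the Pearson correlation between the input
    dissimilarities and the dendrogram's cophenetic distances (1.0 for an
    exactly ultrametric input). The agglomerative coefficient is the mean of
    1 - h_first(i)/h_max over leaves i, where h_first(i) is the height at
    which leaf i first merges.
    """
    if dist.ids != dendrogram.leaf_ids:
        raise ValueError("distance matrix and dendrogram label mismatch")
    condensed = squareform(dist.d, checks=False)
    coph_corr, _ = hierarchy.cophenet(dendrogram.linkage, condensed)
    n = len(dist.ids)
    h_max = dendrogram.linkage[-1, 2]
    # first-merge height per leaf: height of the first linkage row touching it
    merged_at = np.full(n, np.nan)
    for a, b, h, _ in dendrogram.linkage:
        for node in (int(a), int(b)):
            if node < n and np.isnan(merged_at[node]):
                merged_at[node] = h
    agg = float(np.mean(1.0 - merged_at / h_max)) if h_max > 0 else 1.0
    return ClusteringQuality(float(coph_corr), agg)


def to_newick(dendrogram: Dendrogram) -> str:
    """Newick string with branch lengths derived from merge heights.

    A child's branch length is its parent's merge height minus the child's
    own merge height (leaves have height zero), so two leaves merging at
    height h render as ``(a:h,b:h);``.
    """
    tree = hierarchy.to_tree(dendrogram.linkage)

    def fmt(node, parent_height: float) -> str:
        length = parent_height - (0.0 if node.is_leaf() else node.dist)
        if node.is_leaf():
            label = _escape(dendrogram.leaf_ids[node.id])
            return f"{label}:{parent_height:.6g}"
        left = fmt(node.left, node.dist)
        right = fmt(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    left = fmt(tree.left, tree.dist)
    right = fmt(tree.right, tree.dist)
    return f"({left},{right});"


def _escape(label: str) -> str:
    if any(c in label for c in "();:, '\t"):
        return "'" + label.replace("'", "''") + "'"
    return label


def cluster_assignment_table(dendrogram: Dendrogram, n_clusters: int):
    """Cluster assignment at a requested cut as a DataFrame."""
    import pandas as pd

    cut = dendrogram.cut(n_clusters)
    return pd.DataFrame(
        {"id": list(cut), "cluster": [cut[i] for i in cut]}
    ).sort_values(["cluster", "id"], ignore_index=True)
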