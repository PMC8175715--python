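"""Hierarchical clustering of cell lines and EMT-prone cluster labeling.

Samples (columns) are clustered agglomeratively on a gene subset after
per-gene z-score standardization, the heatmap convention.  Defaults are
correlation distance (1 - Pearson) with average linkage; the cluster
whose mean standardized marker expression is highest is designated
EMT-prone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .containers import validate_expression_matrix
from .exceptions import DegenerateInputError, InputError

DISTANCES = ("one_minus_pearson", "euclidean")
LINKAGES = ("average", "complete", "ward")


@dataclass
class LinkageTree:
    """Agglomerative tree over samples (thin wrapper around a scipy
    linkage matrix, remembering leaf IDs and the methods used)."""

    linkage_matrix: np.ndarray  # scipy (n-1, 4) merge sequence
    leaves: list[str]
    distance: str
    linkage: str

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    def merge_heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2].copy()

    def cut(self, k: int) -> pd.Series:
        if not 2 <= k <= self.n_leaves:
            raise InputError(f"k must lie in [2, {self.n_leaves}], got {k}")
        flat = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(flat, index=pd.Index(self.leaves, name="sample_id"), name="cluster")

    def to_newick(self) -> str:
        """Newick string; leaf names are sample IDs, branch lengths are
        differences of merge heights."""
        root = hierarchy.to_tree(self.linkage_matrix)

        def build(node, parent_height):
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.leaves[node.id]}:{length:.6g}"
            left = build(node.left, node.dist)
            right = build(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        return build(root, root.dist) + ";"


def hierarchical_cluster(
    expr: pd.DataFrame,
    gene_subset: list[str] | None = None,
    distance: str = "one_minus_pearson",
    linkage: str = "average",
    standardize: str | bool = "center",
) -> LinkageTree:
    """Cluster samples on a gene subset.

    ``standardize`` is applied per gene before distances: ``"center"``
    (default) removes each gene's mean, ``"zscore"`` additionally scales
    to unit variance, ``"none"`` leaves values untouched (booleans map
    to ``"zscore"``/``"none"``).  Center-only is the default because
    unit-scaling every gene erases the loading differences that let
    correlation distance separate sample groups when a gene's variance
    is dominated by the group signal itself.  Ward linkage requires
    euclidean distance.  A sample constant across the selected genes has
    no defined correlation distance and is rejected by name.
    """
    validate_expression_matrix(expr, "expression")
    if distance not in DISTANCES:
        raise InputError(f"distance must be one of {DISTANCES}, got {distance!r}")
    if linkage not in LINKAGES:
        raise InputError(f"linkage must be one of {LINKAGES}, got {linkage!r}")
    if linkage == "ward" and distance != "euclidean":
        raise InputError("ward linkage requires euclidean distance")
    if expr.shape[1] < 2:
        raise InputError("need >= 2 samples to cluster")
    sub = expr
    if gene_subset is not None:
        keep = expr.index.intersection(pd.Index(gene_subset))
        if len(keep) == 0:
            raise InputError("gene_subset does not intersect the matrix")
        sub = expr.loc[keep]
    if isinstance(standardize, bool):
        standardize = "zscore" if standardize else "none"
    if standardize not in ("none", "center", "zscore"):
        raise InputError(f"standardize must be none/center/zscore, got {standardize!r}")
    values = sub.to_numpy(dtype=float)
    if standardize != "none":
        values = values - values.mean(axis=1, keepdims=True)
    if standardize == "zscore":
        sd = values.std(axis=1, keepdims=True)
        sd[sd == 0] = 1.0
        values = values / sd
    profiles = values.T  # one row per sample
    if distance == "one_minus_pearson":
        spread = profiles.std(axis=1)
        if (spread == 0).any():
            bad = sub.columns[np.flatnonzero(spread == 0)].tolist()
            raise DegenerateInputError(
                f"constant sample profile(s) {bad} have no correlation distance"
            )
        dists = pdist(profiles, metric="correlation")
    else:
        dists = pdist(profiles, metric="euclidean")
    z = hierarchy.linkage(dists, method=linkage)
    return LinkageTree(z, list(sub.columns), distance, linkage)


@dataclass
class ClusterLabels:
    """Flat cluster assignment with the EMT-prone cluster designated."""

    labels: pd.Series  # sample -> cluster id
    emt_prone_cluster: int
    cluster_marker_means: pd.Series  # cluster id -> mean standardized marker expression
    tie: bool = False
    marker_set: list[str] = field(default_factory=list)

    def is_emt_prone(self) -> pd.Series:
        return (self.labels == self.emt_prone_cluster).rename("emt_prone")


def cut_and_label_emt(
    tree: LinkageTree,
    expr: pd.DataFrame,
    marker_set: list[str],
    k: int = 2,
) -> ClusterLabels:
    """Cut the tree into ``k`` clusters and label the EMT-prone one.

    The EMT-prone cluster maximizes the mean per-gene-standardized
    expression of ``marker_set``; an exact tie goes to the lowest
    cluster ID and is flagged.
    """
    labels = tree.cut(k)
    markers = expr.index.intersection(pd.Index(marker_set))
    if len(markers) == 0:
        raise InputError("marker_set does not intersect the expression matrix")
    values = expr.loc[markers, labels.index].to_numpy(dtype=float)
    sd = values.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    z = (values - values.mean(axis=1, keepdims=True)) / sd
    means = {}
    for cluster_id in np.unique(labels.to_numpy()):
        means[int(cluster_id)] = float(z[:, (labels == cluster_id).to_numpy()].mean())
    means = pd.Series(means).sort_index()
    best = means.max()
    winners = means.index[means == best]
    return ClusterLabels(
        labels=labels,
        emt_prone_cluster=int(winners.min()),
        cluster_marker_means=means,
        tie=len(winners) > 1,
        marker_set=list(markers),
    )
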