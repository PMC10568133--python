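"""Hierarchical bi-clustering of the selected feature matrix.

Samples (rows) and features (columns) are clustered independently with Ward
linkage on Euclidean distances of the standard-scaled matrix — the
cluster-map convention.  Flat feature clusters are obtained by a maxclust
cut (default k=5) and relabeled 1..k in dendrogram leaf order.  A cluster
is eligible for enrichment when it contains at least one NMR latent
variable together with at least one functional pathway.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.cluster.hierarchy as sch
from sklearn.metrics import adjusted_rand_score

from .features import BLOCK_LV, BLOCK_MDS, BLOCK_PATHWAY, IntegratedFeatureMatrix
from .io import SampleMetadata

__all__ = [
    "ClusterMap",
    "ClusterAssociation",
    "ward_linkage",
    "cut_feature_clusters",
    "bicluster",
    "extract_associations",
    "group_separation_score",
]


@dataclass
class ClusterMap:
    """Row/column Ward trees plus flat feature-cluster labels for a timepoint."""

    sample_ids: list[str]
    feature_ids: list[str]
    row_linkage: np.ndarray  # scipy (n-1) x 4 merge list over samples
    col_linkage: np.ndarray  # merge list over features
    feature_clusters: dict[str, int]  # labels 1..k, dendrogram leaf order
    sample_order: list[int]
    feature_order: list[int]
    timepoint: str
    blocks: dict[str, str] | None = None


@dataclass
class ClusterAssociation:
    cluster_label: int
    lv_members: set[str]
    pathway_members: set[str]
    mds_members: set[str]
    eligible: bool


def ward_linkage(X: np.ndarray, axis: str = "rows") -> np.ndarray:
    """Ward merge tree over rows or columns of a matrix.

    Agglomeration minimizes the within-cluster variance increase
    (Lance–Williams update on Euclidean distances); ties between equal-cost
    merges break toward the pair containing the smallest original index.
    """
    X = np.asarray(X, dtype=float)
    items = X if axis == "rows" else X.T
    if items.shape[0] < 2:
        raise ValueError("need at least two items to build a linkage")
    return sch.linkage(items, method="ward", metric="euclidean")


def _leaf_order(linkage: np.ndarray, n: int) -> list[int]:
    return list(sch.leaves_list(linkage)) if n > 1 else [0]


def cut_feature_clusters(
    col_linkage: np.ndarray, feature_ids: list[str], k: int
) -> dict[str, int]:
    """Cut the feature dendrogram into exactly k flat clusters.

    Labels 1..k are assigned in dendrogram leaf order, matching how cluster
    maps are annotated left-to-right.
    """
    n = len(feature_ids)
    if not (1 <= k <= n):
        raise ValueError(f"k must lie in [1, {n}]")
    raw = sch.fcluster(col_linkage, t=k, criterion="maxclust")
    order = _leaf_order(col_linkage, n)
    relabel: dict[int, int] = {}
    for leaf in order:
        if raw[leaf] not in relabel:
            relabel[raw[leaf]] = len(relabel) + 1
    return {feature_ids[i]: relabel[raw[i]] for i in range(n)}


def bicluster(X: IntegratedFeatureMatrix, k: int) -> ClusterMap:
    """Independent row and column Ward trees over a scaled feature matrix."""
    row_linkage = ward_linkage(X.values, axis="rows")
    col_linkage = ward_linkage(X.values, axis="columns")
    return ClusterMap(
        sample_ids=list(X.sample_ids),
        feature_ids=list(X.feature_ids),
        row_linkage=row_linkage,
        col_linkage=col_linkage,
        feature_clusters=cut_feature_clusters(col_linkage, X.feature_ids, k),
        sample_order=_leaf_order(row_linkage, len(X.sample_ids)),
        feature_order=_leaf_order(col_linkage, len(X.feature_ids)),
        timepoint=X.timepoint,
        blocks=dict(X.blocks),
    )


def extract_associations(
    cmap: ClusterMap, blocks: dict[str, str] | None = None
) -> list[ClusterAssociation]:
    """Per-cluster block membership and the enrichment-eligibility flag.

    A cluster is eligible exactly when it associates at least one latent
    variable with at least one functional pathway.
    """
    blocks = blocks if blocks is not None else cmap.blocks
    if blocks is None:
        raise ValueError("no block labels available")
    missing = [f for f in cmap.feature_ids if f not in blocks]
    if missing:
        raise ValueError(f"features without block labels: {missing}")
    labels = sorted(set(cmap.feature_clusters.values()))
    out = []
    for label in labels:
        members = [f for f in cmap.feature_ids if cmap.feature_clusters[f] == label]
        lvs = {f for f in members if blocks[f] == BLOCK_LV}
        pws = {f for f in members if blocks[f] == BLOCK_PATHWAY}
        axes = {f for f in members if blocks[f] == BLOCK_MDS}
        out.append(
            ClusterAssociation(
                cluster_label=label,
                lv_members=lvs,
                pathway_members=pws,
                mds_members=axes,
                eligible=bool(lvs) and bool(pws),
            )
        )
    return out


def group_separation_score(cmap: ClusterMap, meta: SampleMetadata) -> float:
    """Adjusted Rand index of the k=#groups sample-dendrogram cut vs groups.

    Quantifies how completely the sample dendrogram separates the treatment
    groups (1 = perfect separation, ~0 = chance).
    """
    groups = meta.groups_of(cmap.sample_ids)
    k = len(set(groups))
    flat = sch.fcluster(cmap.row_linkage, t=k, criterion="maxclust")
    return float(adjusted_rand_score(groups, flat))
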