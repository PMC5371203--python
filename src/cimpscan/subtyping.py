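"""Hierarchical clustering of samples and CIMP-H/L/N label assignment.

All samples (tumour and normal) are clustered on the selected probe panel
with Euclidean distance and complete linkage. Labels follow a fixed,
reproducible cut rule: the dendrogram is cut into two branches, the
branch with the lower mean beta is "normal-like" (tumours falling there
are CIMP-N, the least methylated subtype), and the tumour-like branch is
cut into three subclusters ranked by descending mean beta to give
CIMP-H, CIMP-L and CIMP-N. Normal samples landing in the tumour-like
branch are flagged and excluded from downstream analysis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .preprocess import SampleSheet

CIMP_H, CIMP_L, CIMP_N = "CIMP-H", "CIMP-L", "CIMP-N"


@dataclass
class Dendrogram:
    """Agglomerative merge tree over samples.

    ``linkage_matrix`` is the standard (n-1) x 4 encoding: children ids,
    merge height, cluster size. Leaves are numbered by position in
    ``sample_ids``.
    """

    sample_ids: list[str]
    linkage_matrix: np.ndarray
    metric: str = "euclidean"
    linkage: str = "complete"

    def __post_init__(self) -> None:
        n = len(self.sample_ids)
        if self.linkage_matrix.shape != (n - 1, 4):
            raise ValueError("linkage matrix must have n-1 merges")

    def leaf_order(self) -> list[str]:
        order = hierarchy.leaves_list(self.linkage_matrix)
        return [self.sample_ids[i] for i in order]

    def cut(self, k: int) -> pd.Series:
        """Partition into k clusters (maxclust criterion); ids arbitrary but stable."""
        labels = hierarchy.fcluster(self.linkage_matrix, t=k, criterion="maxclust")
        return pd.Series(labels, index=self.sample_ids)

    def to_dict(self) -> dict:
        return {
            "sample_ids": self.sample_ids,
            "merges": self.linkage_matrix.tolist(),
            "metric": self.metric,
            "linkage": self.linkage,
        }


def complete_linkage_cluster(X: pd.DataFrame) -> Dendrogram:
    """Cluster samples (rows) on their beta profiles.

    Uses Euclidean distance with complete linkage; scipy's agglomeration
    is deterministic for a given input order, with ties resolved towards
    the smallest distance entry first encountered.
    """
    if len(X) < 2:
        raise ValueError("need at least two samples")
    if X.isna().any().any():
        raise ValueError("missing values in selected probes; filter upstream")
    Z = hierarchy.linkage(pdist(X.values, metric="euclidean"), method="complete")
    return Dendrogram(sample_ids=list(X.index), linkage_matrix=Z)


@dataclass
class CimpAssignment:
    """Per-sample subtype labels plus cluster-level diagnostics."""

    labels: pd.Series  # tumour sample -> CIMP-H / CIMP-L / CIMP-N
    excluded_normals: list[str] = field(default_factory=list)
    tumours_in_normal_branch: list[str] = field(default_factory=list)
    cluster_means: dict[str, float] = field(default_factory=dict)

    def tumours_of(self, label: str) -> list[str]:
        return self.labels.index[self.labels == label].tolist()

    def group_sizes(self) -> dict[str, int]:
        return self.labels.value_counts().to_dict()


def _branch_subclusters(dend: Dendrogram, branch: set[str], k: int) -> pd.Series:
    """Cut a dendrogram branch into k subclusters.

    Raising the global cluster count splits one cluster at a time in
    height order; since a branch is a subtree, the first k-1 splits that
    affect the branch partition it exactly as cutting its own subtree.
    """
    n = len(dend.sample_ids)
    for k_global in range(k, n + 1):
        part = dend.cut(k_global)
        sub = part[part.index.isin(branch)]
        if sub.nunique() == k:
            return sub
        if sub.nunique() > k:  # tied merge heights: fall back below
            break
    raise TiedCutError("tied merge heights prevent a nested branch cut")


class TiedCutError(RuntimeError):
    pass


def assign_cimp_labels(
    dend: Dendrogram,
    sheet: SampleSheet,
    X: pd.DataFrame,
    cut_mode: str = "nested",
    k_tumour_clusters: int = 3,
) -> CimpAssignment:
    """Assign CIMP-H/L/N to every tumour from the dendrogram geometry.

    ``nested`` mode (default) cuts at k=2 and then into
    ``k_tumour_clusters`` within the tumour-like branch; ``flat`` mode
    cuts the whole tree into ``k_tumour_clusters + 1`` clusters at once.
    Cluster ranking by mean beta over the selected probes is descending:
    highest -> CIMP-H, middle -> CIMP-L, lowest -> CIMP-N.
    """
    tissues = sheet.table["tissue"].reindex(dend.sample_ids)
    if tissues.isna().any():
        raise ValueError("dendrogram samples missing from sample sheet")
    sample_means = X.mean(axis=1).reindex(dend.sample_ids)

    if cut_mode == "nested":
        two = dend.cut(2)
        branch_means = sample_means.groupby(two).mean()
        normal_branch_id = branch_means.idxmin()
        normal_branch = set(two.index[two == normal_branch_id])
        tumour_branch = set(two.index) - normal_branch
        tumours_in_normal = [
            s for s in normal_branch if tissues[s] == "tumour"
        ]
        if sum(tissues[s] == "tumour" for s in tumour_branch) == 0:
            raise ValueError("no tumour-like branch: all tumours cluster as normal")
        if len(tumour_branch) < k_tumour_clusters:
            raise ValueError(
                f"tumour-like branch has {len(tumour_branch)} samples; "
                f"cannot form {k_tumour_clusters} subclusters"
            )
        try:
            sub = _branch_subclusters(dend, tumour_branch, k_tumour_clusters)
        except TiedCutError:
            # degenerate tie in merge heights: recluster the branch alone
            branch_ids = [s for s in dend.sample_ids if s in tumour_branch]
            sub = complete_linkage_cluster(X.loc[branch_ids]).cut(k_tumour_clusters)
    elif cut_mode == "flat":
        part = dend.cut(k_tumour_clusters + 1)
        cluster_means = sample_means.groupby(part).mean()
        normal_branch_id = cluster_means.idxmin()
        normal_branch = set(part.index[part == normal_branch_id])
        tumours_in_normal = [s for s in normal_branch if tissues[s] == "tumour"]
        sub = part[~part.index.isin(normal_branch)]
        if sub.nunique() < k_tumour_clusters:
            raise ValueError("flat cut produced too few tumour clusters")
    else:
        raise ValueError(f"unknown cut_mode {cut_mode!r}")

    sub_means = sample_means.groupby(sub).mean().sort_values(ascending=False)
    ordered_labels = [CIMP_H, CIMP_L, CIMP_N][: len(sub_means)]
    cluster_to_label = dict(zip(sub_means.index, ordered_labels))

    labels: dict[str, str] = {}
    excluded_normals: list[str] = []
    for s in dend.sample_ids:
        if s in normal_branch:
            if tissues[s] == "tumour":
                labels[s] = CIMP_N
        else:
            if tissues[s] == "normal":
                excluded_normals.append(s)
            else:
                labels[s] = cluster_to_label[sub[s]]

    cluster_means = {
        cluster_to_label[c]: float(m) for c, m in sub_means.items()
    }
    cluster_means["normal_branch"] = float(
        sample_means[sample_means.index.isin(normal_branch)].mean()
    )
    label_series = pd.Series(labels, name="cimp_label")
    label_series = label_series.reindex(
        [s for s in dend.sample_ids if s in labels]
    )
    return CimpAssignment(
        labels=label_series,
        excluded_normals=excluded_normals,
        tumours_in_normal_branch=tumours_in_normal,
        cluster_means=cluster_means,
    )
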