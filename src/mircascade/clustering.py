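"""Hierarchical clustering of selected genes into expression clusters.

Default convention for expression profiles: average linkage on 1 - Pearson
correlation distance.  Complete linkage and Euclidean distance are available.
The merge history (scipy linkage matrix) is kept in the result for audit and
optional tree export.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import pdist

from .expression import ExpressionMatrix

LINKAGES = ("average", "complete")
DISTANCES = {"euclidean": "euclidean", "one_minus_pearson": "correlation"}


@dataclass
class ClusterResult:
    """Gene→cluster labels plus the agglomeration history that produced them."""

    labels: dict[str, int]
    linkage: str
    distance: str
    merge_history: np.ndarray  # scipy linkage matrix (n-1) x 4
    k: int

    def __post_init__(self) -> None:
        heights = self.merge_history[:, 2]
        if (np.diff(heights) < -1e-9).any():
            raise ValueError("merge heights are not nondecreasing")

    def members(self, cluster: int) -> set[str]:
        return {g for g, c in self.labels.items() if c == cluster}

    @property
    def clusters(self) -> list[int]:
        return sorted(set(self.labels.values()))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.labels), "cluster": list(self.labels.values())}
        ).set_index("gene")


def hierarchical_cluster(
    m: ExpressionMatrix,
    genes=None,
    linkage: str = "average",
    distance: str = "one_minus_pearson",
    k: int = 2,
) -> ClusterResult:
    """Agglomerative clustering of gene expression profiles, cut into k groups.

    Deterministic given the gene input order; duplicate profiles merge at
    height 0 and always co-cluster.
    """
    if linkage not in LINKAGES:
        raise ValueError(f"linkage must be one of {LINKAGES}")
    if distance not in DISTANCES:
        raise ValueError(f"distance must be one of {tuple(DISTANCES)}")
    if genes is not None:
        m = m.subset_genes(genes)
    gene_ids = list(m.gene_ids)
    n = len(gene_ids)
    if k > n:
        raise ValueError(f"k={k} exceeds number of genes ({n})")
    X = m.values.to_numpy(dtype=float)
    if not np.isfinite(X).all():
        raise ValueError("expression values contain missing/non-finite entries")
    if distance == "one_minus_pearson" and (X.std(axis=1) == 0).any():
        flat = [gene_ids[i] for i in np.where(X.std(axis=1) == 0)[0]]
        raise ValueError(
            f"constant profiles have undefined correlation distance: {flat[:5]}"
        )
    d = pdist(X, metric=DISTANCES[distance])
    d = np.maximum(d, 0.0)  # correlation metric can go -eps numerically
    Z = hierarchy.linkage(d, method=linkage)
    flat = hierarchy.fcluster(Z, t=k, criterion="maxclust")
    return ClusterResult(
        labels=dict(zip(gene_ids, (int(c) for c in flat))),
        linkage=linkage,
        distance=distance,
        merge_history=Z,
        k=k,
    )
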