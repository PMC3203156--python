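"""Hierarchical clustering of samples and donor-level cluster purity.

Samples are clustered on a gene subset (typically the genes associated with
cell-count covariates) using correlation distance ``1 - Pearson(r)`` between
sample profiles and average linkage — the standard microarray convention.
Cutting the tree into ``k`` clusters and comparing against donor labels with
the adjusted Rand index turns "samples cluster perfectly by donor" into a
quantitative statement: ARI = 1 iff the partition matches the donors exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score


@dataclass
class Dendrogram:
    """Sample dendrogram: scipy linkage matrix plus bookkeeping."""

    linkage_matrix: np.ndarray  # (n-1, 4) scipy format
    sample_ids: list[str]  # order used for the distance matrix (sorted)
    leaf_order: list[str]
    linkage: str = "average"
    distance: str = "1 - pearson"

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def heights(self) -> np.ndarray:
        return self.linkage_matrix[:, 2]


def hclust_samples(mat: pd.DataFrame) -> Dendrogram:
    """Cluster sample columns of a genes x samples matrix.

    Gene rows are centered before computing sample-sample correlations, so
    the tree depends only on each gene's deviations across samples, never on
    its baseline intensity.  Sample columns are processed in sorted-ID order
    so that distance ties resolve deterministically.  A sample whose profile
    has zero variance has no defined correlation and is rejected by name.
    """
    if mat.shape[1] < 2:
        raise ValueError("need at least 2 samples to cluster")
    if mat.shape[0] < 1:
        raise ValueError("gene subset is empty")
    mat = mat[sorted(mat.columns)]
    values = mat.to_numpy(float)
    sds = values.std(axis=0)
    if np.any(sds == 0):
        bad = [mat.columns[i] for i in np.flatnonzero(sds == 0)]
        raise ValueError(f"zero-variance sample profile(s): {bad}")
    values = values - values.mean(axis=1, keepdims=True)
    corr = np.corrcoef(values.T)
    dist = 1.0 - corr
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)  # symmetrize rounding noise
    Z = hierarchy.linkage(squareform(dist, checks=False), method="average")
    leaves = hierarchy.leaves_list(Z)
    return Dendrogram(
        linkage_matrix=Z,
        sample_ids=list(mat.columns),
        leaf_order=[mat.columns[i] for i in leaves],
    )


@dataclass
class DonorPurity:
    """Agreement between a k-cluster tree cut and donor labels."""

    ari: float
    k: int
    assignments: pd.Series  # sample -> cluster id
    composition: pd.DataFrame  # clusters x donors contingency table


def donor_purity(dend: Dendrogram, donor_labels, k: int) -> DonorPurity:
    """Cut the dendrogram into ``k`` clusters and score against donors.

    ``donor_labels`` maps sample ID to donor (mapping or pandas Series);
    every sample in the dendrogram must be labelled.
    """
    if not 2 <= k <= dend.n:
        raise ValueError(f"k={k} out of range 2..{dend.n}")
    labels = pd.Series(donor_labels)
    missing = [s for s in dend.sample_ids if s not in labels.index]
    if missing:
        raise ValueError(f"samples without donor label: {missing}")
    labels = labels.reindex(dend.sample_ids)
    clusters = hierarchy.fcluster(dend.linkage_matrix, t=k, criterion="maxclust")
    ari = float(adjusted_rand_score(labels.to_numpy(), clusters))
    assignments = pd.Series(clusters, index=dend.sample_ids, name="cluster")
    composition = pd.crosstab(assignments, labels)
    return DonorPurity(ari=ari, k=k, assignments=assignments, composition=composition)
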