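"""PCA of expression matrices via SVD of the per-gene-centered data.

With genes on the rows and samples on the columns, each gene row is centered
to mean zero across samples and the centered matrix is decomposed as
``X = U D V^T``.  The columns of ``V`` (the principal components) are
length-``n`` patterns across samples; the share of total variance carried by
PC ``k`` is ``p_k = d_k^2 / sum_j d_j^2``.  Row-centering puts the all-ones
vector in the null space, so every PC has mean zero across samples — the
property the downstream regression-R2 machinery relies on — and at most
``n - 1`` components are nonzero.  All nonzero components are retained; no
truncation is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_is_fitted


class ExpressionPCA(BaseEstimator, TransformerMixin):
    """Full-rank PCA over a samples x genes matrix with per-gene centering.

    Unlike truncated decompositions, every component with a nonzero singular
    value is retained so that variance shares sum to 1.  Signs are fixed by
    flipping each sample-space component so its largest-magnitude entry is
    positive, making the output deterministic.

    Attributes
    ----------
    mean_ : (n_genes,) per-gene means removed before decomposition.
    components_ : (r, n_genes) gene-space singular vectors (rows of ``U^T``).
    sample_components_ : (n_samples, r) unit-norm sample-space PCs (``V``).
    singular_values_ : (r,) descending singular values.
    explained_variance_ratio_ : (r,) variance shares ``p_k``.
    """

    def __init__(self, rank_tol: float = 1e-12):
        self.rank_tol = rank_tol

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("expected a 2-D samples x genes matrix")
        n, m = X.shape
        if n < 2 or m < 1:
            raise ValueError("need at least 2 samples and 1 gene")
        if not np.isfinite(X).all():
            raise ValueError("expression matrix contains non-finite values")
        self.mean_ = X.mean(axis=0)
        Xc = X - self.mean_
        if not np.any(Xc):
            raise ValueError("matrix has zero total variance; PCA undefined")
        # Xc = V diag(d) U^T in the genes x samples convention
        V, d, Ut = np.linalg.svd(Xc, full_matrices=False)
        keep = d > self.rank_tol * d[0]
        V, d, Ut = V[:, keep], d[keep], Ut[keep]
        # sign convention: largest-|entry| of each sample-space PC positive
        flip = np.sign(V[np.abs(V).argmax(axis=0), np.arange(V.shape[1])])
        V *= flip
        Ut *= flip[:, None]
        self.sample_components_ = V
        self.components_ = Ut
        self.singular_values_ = d
        self.explained_variance_ratio_ = d**2 / np.sum(d**2)
        self.n_samples_, self.n_features_in_ = n, m
        return self

    def transform(self, X):
        check_is_fitted(self, "components_")
        X = np.asarray(X, dtype=float)
        return (X - self.mean_) @ self.components_.T

    @property
    def rank_(self) -> int:
        check_is_fitted(self, "components_")
        return len(self.singular_values_)


@dataclass
class PCADecomposition:
    """Domain view of a fitted decomposition of a genes x samples matrix."""

    gene_ids: list[str]
    sample_ids: list[str]
    U: np.ndarray  # m x r gene loadings
    d: np.ndarray  # r singular values, descending
    V: np.ndarray  # n x r sample-space PCs, unit norm, zero mean
    p: np.ndarray  # r variance proportions
    row_means: pd.Series

    @property
    def m(self) -> int:
        return len(self.gene_ids)

    @property
    def n(self) -> int:
        return len(self.sample_ids)

    @property
    def r(self) -> int:
        return len(self.d)

    def pc(self, k: int) -> np.ndarray:
        """1-based access to the k-th principal component."""
        if not 1 <= k <= self.r:
            raise IndexError(f"PC index {k} out of range 1..{self.r}")
        return self.V[:, k - 1]

    def reconstruct(self) -> pd.DataFrame:
        centered = self.U @ np.diag(self.d) @ self.V.T
        return pd.DataFrame(
            centered + self.row_means.to_numpy()[:, None],
            index=self.gene_ids,
            columns=self.sample_ids,
        )

    def components_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.V,
            index=self.sample_ids,
            columns=[f"PC{k}" for k in range(1, self.r + 1)],
        )

    def variance_table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "pc": np.arange(1, self.r + 1),
                "singular_value": self.d,
                "variance_proportion": self.p,
                "cumulative": np.cumsum(self.p),
            }
        ).set_index("pc")


def center_rows(mat: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Center each gene row to mean zero across samples; return the means."""
    values = mat.to_numpy(dtype=float)
    if not np.isfinite(values).all():
        raise ValueError("expression matrix contains non-finite values")
    means = values.mean(axis=1)
    centered = pd.DataFrame(
        values - means[:, None], index=mat.index, columns=mat.columns
    )
    return centered, pd.Series(means, index=mat.index, name="row_mean")


def pca(mat: pd.DataFrame) -> PCADecomposition:
    """Decompose a genes x samples log2 matrix into principal components."""
    est = ExpressionPCA().fit(mat.to_numpy(dtype=float).T)
    return PCADecomposition(
        gene_ids=list(mat.index),
        sample_ids=list(mat.columns),
        U=est.components_.T,
        d=est.singular_values_,
        V=est.sample_components_,
        p=est.explained_variance_ratio_,
        row_means=pd.Series(est.mean_, index=mat.index, name="row_mean"),
    )


def cumulative_variance(dec: PCADecomposition, k: int) -> float:
    """Fraction of total variance captured by the top-k PCs."""
    if not 1 <= k <= dec.r:
        raise IndexError(f"k={k} out of range 1..{dec.r}")
    return float(dec.p[:k].sum())
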