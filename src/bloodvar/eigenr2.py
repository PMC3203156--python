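"""The Eigen-R2 statistic: variance of an expression matrix explained by a covariate.

Each principal component ``v_k`` (a length-``n`` pattern across samples) is
regressed on the covariate's design matrix by least squares, giving a
coefficient of determination

    R2_k = sum_i (vhat_ki - mean(vhat_k))^2 / sum_i (v_ki - mean(v_k))^2.

Because PC ``k`` carries a share ``p_k = d_k^2 / sum d_j^2`` of the total
variance and distinct PCs are uncorrelated, the explained shares add, and

    eigen-R2 = sum_k p_k * R2_k

estimates the fraction of total expression variance explained by the
covariate.  When every PC is used this equals the exact Frobenius identity
``||Xc P||_F^2 / ||Xc||_F^2`` with ``Xc`` the row-centered matrix and ``P``
the projection onto the centered design span — the variance-weighted mean of
gene-wise R2 values.

For small cohorts the raw statistic is biased upward by chance fitting; the
adjusted form

    adjusted = 1 - (1 - raw) * (n - df0) / (n - df1)

penalizes the degrees of freedom spent beyond the intercept-only null model
(``df0 = 1`` by default) and may be negative.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from .containers import SampleCovariates
from .design import DesignError, VariableModel, build_design
from .pca import PCADecomposition, pca


@dataclass
class EigenR2Result:
    """Aggregated Eigen-R2 with the per-PC breakdown retained."""

    model: VariableModel
    pc_r2: np.ndarray
    weights: np.ndarray
    raw: float
    adjusted: float
    df0: int
    df1: int
    n: int

    def summary(self) -> dict:
        return {
            "variables": list(self.model.variables),
            "confounders": list(self.model.confounders),
            "raw": self.raw,
            "adjusted": self.adjusted,
            "df0": self.df0,
            "df1": self.df1,
            "n": self.n,
        }


def _fit_r2(v: np.ndarray, X: np.ndarray) -> float:
    v = np.asarray(v, dtype=float)
    centered = v - v.mean()
    ss_tot = float(centered @ centered)
    if ss_tot == 0:
        raise ValueError("PC vector has zero variance; R2 undefined")
    coef, *_ = np.linalg.lstsq(X, v, rcond=None)
    fitted = X @ coef
    dev = fitted - fitted.mean()
    r2 = float(dev @ dev) / ss_tot
    return min(r2, 1.0)  # guard rounding just above 1


def pc_r2(
    v_k: np.ndarray, model: VariableModel, cov: SampleCovariates
) -> float:
    """R2 of one principal component regressed on the model's design."""
    design = build_design(model, cov)
    n, df1 = design.shape
    if len(v_k) != n:
        raise ValueError(f"PC has length {len(v_k)}, design has {n} rows")
    if n <= df1:
        raise DesignError(f"n={n} samples cannot fit a {df1}-column design")
    return _fit_r2(np.asarray(v_k, dtype=float), design.to_numpy(float))


def adjusted_eigen_r2(raw: float, n: int, df0: int = 1, df1: int = 2) -> float:
    """Small-sample adjustment of an (eigen-)R2 value.

    ``df0`` and ``df1`` are the degrees of freedom spent by the null and
    target models (intercept-only null: ``df0 = 1``).  The adjusted value
    never exceeds the raw one and may be negative.
    """
    if not (df1 >= df0 >= 1):
        raise ValueError(f"need df1 >= df0 >= 1, got df0={df0}, df1={df1}")
    if n <= df1:
        raise ValueError(f"need n > df1, got n={n}, df1={df1}")
    return 1.0 - (1.0 - raw) * (n - df0) / (n - df1)


def eigen_r2(
    dec: PCADecomposition,
    model: VariableModel,
    cov: SampleCovariates,
    df0: int = 1,
) -> EigenR2Result:
    """Eigen-R2 of a covariate model over all retained PCs.

    Sample identity is checked by ID, not position: the decomposition and
    the covariate table must list the same samples in the same order.
    """
    if list(dec.sample_ids) != list(cov.sample_ids):
        raise ValueError(
            "sample order mismatch between decomposition and covariates "
            f"(first difference at position "
            f"{next(i for i, (a, b) in enumerate(zip(dec.sample_ids, cov.sample_ids)) if a != b) if len(dec.sample_ids) == len(cov.sample_ids) else 'length'})"
        )
    design = build_design(model, cov)
    n, df1 = design.shape
    # saturated designs (df1 == n) are permitted: every R2_k is 1 and only
    # the raw statistic is defined
    X = design.to_numpy(float)
    r2 = np.array([_fit_r2(dec.V[:, k], X) for k in range(dec.r)])
    raw = float(np.dot(dec.p, r2))
    if n > df1:
        adjusted = adjusted_eigen_r2(raw, n, df0=df0, df1=df1)
    else:
        adjusted = float("nan")
    return EigenR2Result(
        model=model,
        pc_r2=r2,
        weights=dec.p.copy(),
        raw=raw,
        adjusted=adjusted,
        df0=df0,
        df1=df1,
        n=n,
    )


@dataclass
class PartialEigenR2:
    """Confounder-adjusted variance share: full minus reduced model."""

    fraction: float
    full: EigenR2Result
    reduced: EigenR2Result | None


def partial_eigen_r2(
    dec: PCADecomposition,
    variable: str | Sequence[str],
    confounders: Sequence[str],
    cov: SampleCovariates,
) -> PartialEigenR2:
    """Variance share of ``variable`` beyond the listed confounders.

    Computed sequentially as adjusted(full model) - adjusted(confounders
    only), floored at zero; both component fits are returned so the
    full-model value remains inspectable.
    """
    full_model = VariableModel(variable, confounders)  # validates duplication
    full = eigen_r2(dec, full_model, cov)
    if not tuple(confounders):
        return PartialEigenR2(fraction=full.adjusted, full=full, reduced=None)
    reduced = eigen_r2(dec, VariableModel(tuple(confounders)), cov)
    fraction = max(full.adjusted - reduced.adjusted, 0.0)
    return PartialEigenR2(fraction=fraction, full=full, reduced=reduced)


class EigenR2(BaseEstimator):
    """Estimator interface: fraction of expression variance tied to a covariate.

    ``fit(X, covariates)`` takes a samples x genes matrix (the sklearn
    orientation; a genes x samples frame should be transposed first) and a
    :class:`SampleCovariates` table aligned to its rows.  After fitting,
    ``raw_`` and ``adjusted_`` hold the aggregated statistic, ``pc_r2_`` the
    per-PC breakdown and, when confounders are declared, ``partial_`` the
    confounder-adjusted share.
    """

    def __init__(self, variable: str | Sequence[str] = None, confounders: Sequence[str] = ()):
        self.variable = variable
        self.confounders = confounders

    def fit(self, X, covariates: SampleCovariates):
        if self.variable is None:
            raise ValueError("variable must be set before fitting")
        if isinstance(X, pd.DataFrame):
            frame = X.T
        else:
            frame = pd.DataFrame(
                np.asarray(X, dtype=float).T, columns=covariates.sample_ids
            )
        dec = pca(frame)
        part = partial_eigen_r2(dec, self.variable, tuple(self.confounders), covariates)
        result = part.full
        self.decomposition_ = dec
        self.result_ = result
        self.pc_r2_ = result.pc_r2
        self.variance_ratio_ = result.weights
        self.raw_ = result.raw
        self.adjusted_ = result.adjusted
        self.partial_ = part.fraction
        self.df0_, self.df1_, self.n_ = result.df0, result.df1, result.n
        return self

    def score(self, X=None, y=None) -> float:
        check_is_fitted(self, "raw_")
        return self.adjusted_
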