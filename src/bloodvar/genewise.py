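"""Per-gene linear screening of expression on a covariate.

Every gene's log2 profile is regressed on the same design (intercept,
variable of interest, optional confounders) by ordinary least squares.  By
default the residual variances are moderated across genes in the
empirical-Bayes fashion of the limma pipeline: the gene-wise variances
``s2_g`` on ``d_g`` residual degrees of freedom are shrunk toward a prior
variance ``s0^2`` with prior degrees of freedom ``d0``,

    s2_post = (d0 * s0^2 + d_g * s2_g) / (d0 + d_g),

and the moderated t-statistic is referenced to ``d0 + d_g`` degrees of
freedom.  The hyperparameters are estimated by method of moments on the log
variances (matching the scaled-F model of the moderated-t literature).
Multiple testing is controlled by the Benjamini-Hochberg step-up procedure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import digamma, polygamma
from sklearn.base import BaseEstimator

from .containers import SampleCovariates
from .design import DesignError, VariableModel, build_design, variable_columns


@dataclass
class GenewiseResult:
    """Per-gene statistics for the variable of interest."""

    table: pd.DataFrame  # coef, se, t, df, pvalue, qvalue per gene
    model: VariableModel
    moderated: bool
    prior_df: float | None = None
    prior_var: float | None = None


def _trigamma_inverse(y: float) -> float:
    """Solve trigamma(x) = y for x > 0 (Newton iteration on 1/trigamma)."""
    if y <= 0:
        return np.inf
    if y > 1e7:
        return 1.0 / np.sqrt(y)
    if y < 1e-6:
        return 1.0 / y
    x = 0.5 + 1.0 / y
    for _ in range(50):
        tri = polygamma(1, x)
        dif = tri * (1.0 - tri / y) / polygamma(2, x)
        x += dif
        if abs(dif) / x < 1e-8:
            break
    return float(x)


def moderate_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Shrink gene-wise variances toward a common prior.

    Returns ``(s2_post, d0, s0_sq)``.  Genes with exactly zero residual
    variance are excluded from hyperparameter estimation; their posterior is
    the pure prior contribution.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        raise ValueError("need at least 2 genes with positive residual variance")
    z = np.log(s2[ok])
    e = z - digamma(df / 2.0) + np.log(df / 2.0)
    e_mean = e.mean()
    e_var = e.var(ddof=1) - polygamma(1, df / 2.0)
    if e_var > 0:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = float(np.exp(e_mean + digamma(d0 / 2.0) - np.log(d0 / 2.0)))
    else:
        d0 = np.inf
        s0_sq = float(np.exp(e_mean))
    if np.isinf(d0):
        s2_post = np.full_like(s2, s0_sq)
    else:
        s2_post = (d0 * s0_sq + df * s2) / (d0 + df)
    return s2_post, float(d0), s0_sq


def fit_genewise(
    mat: pd.DataFrame,
    model: VariableModel,
    cov: SampleCovariates,
    moderate: bool = True,
) -> GenewiseResult:
    """OLS of every gene's profile on the model design.

    ``mat`` is genes x samples with columns matching the covariate table's
    sample order.  The reported coefficient is that of the variable of
    interest, which must encode to a single design column (a standardized
    continuous covariate or a binary factor).
    """
    if list(mat.columns) != list(cov.sample_ids):
        raise ValueError("sample order mismatch between expression and covariates")
    design = build_design(model, cov)
    var_cols = variable_columns(model, design)
    if len(var_cols) != 1:
        raise DesignError(
            f"gene-wise screening needs a single-column variable of interest; "
            f"{model.variables} encodes to columns {var_cols}"
        )
    X = design.to_numpy(float)
    n, p = X.shape
    df_resid = n - p
    if df_resid <= 0:
        raise DesignError(f"zero residual degrees of freedom (n={n}, design columns={p})")
    j = design.columns.get_loc(var_cols[0])

    Y = mat.to_numpy(float).T  # samples x genes
    xtx_inv = np.linalg.inv(X.T @ X)
    coef = xtx_inv @ X.T @ Y  # p x genes
    resid = Y - X @ coef
    s2 = (resid**2).sum(axis=0) / df_resid

    if moderate:
        s2_used, d0, s0_sq = moderate_variances(s2, df_resid)
        df_total = d0 + df_resid
    else:
        s2_used, d0, s0_sq = s2, None, None
        df_total = float(df_resid)

    se = np.sqrt(s2_used * xtx_inv[j, j])
    beta = coef[j]
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, beta / se, np.where(beta == 0, 0.0, np.inf * np.sign(beta)))
    if np.isinf(df_total):
        pvals = 2.0 * stats.norm.sf(np.abs(t))
    else:
        pvals = 2.0 * stats.t.sf(np.abs(t), df_total)
    pvals = np.clip(pvals, np.finfo(float).tiny, 1.0)

    table = pd.DataFrame(
        {
            "coef": beta,
            "se": se,
            "t": t,
            "df": df_total,
            "pvalue": pvals,
            "qvalue": bh_fdr(pvals),
        },
        index=mat.index,
    )
    return GenewiseResult(
        table=table,
        model=model,
        moderated=moderate,
        prior_df=d0,
        prior_var=s0_sq,
    )


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values, capped
    at 1.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.ndim != 1:
        raise ValueError("pvalues must be 1-D")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def select_genes(res: GenewiseResult, fdr: float = 0.01) -> list[str]:
    """Genes with q-value below the FDR threshold, ordered by ascending p."""
    if not 0 < fdr <= 1:
        raise ValueError(f"fdr threshold must lie in (0, 1], got {fdr}")
    hits = res.table[res.table["qvalue"] < fdr]
    return list(hits.sort_values("pvalue").index)


class GenewiseLinearModel(BaseEstimator):
    """Estimator interface for the per-gene screen.

    ``fit(X, covariates)`` takes a samples x genes frame (columns = gene
    IDs); fitted attributes mirror :class:`GenewiseResult` columns as arrays
    aligned to the gene axis.
    """

    def __init__(
        self,
        variable: str | None = None,
        confounders=(),
        moderate: bool = True,
        fdr: float = 0.01,
    ):
        self.variable = variable
        self.confounders = confounders
        self.moderate = moderate
        self.fdr = fdr

    def fit(self, X, covariates: SampleCovariates):
        if self.variable is None:
            raise ValueError("variable must be set before fitting")
        if isinstance(X, pd.DataFrame):
            mat = X.T
        else:
            mat = pd.DataFrame(np.asarray(X, dtype=float).T, columns=covariates.sample_ids)
        res = fit_genewise(
            mat, VariableModel(self.variable, tuple(self.confounders)), covariates,
            moderate=self.moderate,
        )
        self.result_ = res
        self.coef_ = res.table["coef"].to_numpy()
        self.t_ = res.table["t"].to_numpy()
        self.pvalues_ = res.table["pvalue"].to_numpy()
        self.qvalues_ = res.table["qvalue"].to_numpy()
        self.prior_df_ = res.prior_df
        self.prior_var_ = res.prior_var
        self.selected_ = select_genes(res, self.fdr)
        return self
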