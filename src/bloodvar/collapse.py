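"""Probeset-to-gene collapsing and the covariate rank-correlation summary.

Microarray designs interrogate most genes with several probesets.  To obtain
one profile per gene, probesets without an Entrez annotation are discarded
and, among probesets sharing an Entrez ID, only the one with the largest
interquartile range (IQR) across samples is kept — the most variable
probeset is assumed to carry the most signal.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .containers import SampleCovariates


class AnnotationError(ValueError):
    """Raised in strict mode when a probeset lacks an annotation row."""


def _iqr(values: np.ndarray) -> float:
    # type-7 quantiles (linear interpolation), numpy's default
    q75, q25 = np.percentile(values, [75, 25])
    return float(q75 - q25)


def collapse_by_iqr(
    mat: pd.DataFrame,
    annot: pd.DataFrame,
    missing: str = "drop",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Collapse a probeset matrix to one row per Entrez gene by maximal IQR.

    Parameters
    ----------
    mat:
        Probesets x samples log2 matrix.
    annot:
        Annotation frame indexed by probeset with columns ``entrez`` and
        ``symbol`` (NaN = unannotated).
    missing:
        Policy for probesets absent from the annotation table: ``"drop"``
        removes them with a warning, ``"strict"`` raises.

    Returns
    -------
    (gene_matrix, report):
        ``gene_matrix`` is genes x samples keyed by Entrez ID.  ``report``
        records, per gene, the retained probeset, its IQR and the number of
        candidate probesets.

    Ties in IQR are broken toward the lexicographically smallest probeset ID,
    so the collapse is deterministic.
    """
    if missing not in ("drop", "strict"):
        raise ValueError(f"unknown missing-annotation policy {missing!r}")
    unannotated = mat.index.difference(annot.index)
    if len(unannotated) > 0:
        if missing == "strict":
            raise AnnotationError(
                f"{len(unannotated)} probesets missing from annotation, "
                f"e.g. {list(unannotated[:3])}"
            )
        warnings.warn(
            f"dropping {len(unannotated)} probesets absent from annotation",
            stacklevel=2,
        )
    probesets = mat.index.intersection(annot.index)
    entrez = annot.loc[probesets, "entrez"]
    keep_mask = entrez.notna()
    probesets = probesets[keep_mask]
    entrez = entrez[keep_mask]

    iqr = pd.Series(
        {p: _iqr(mat.loc[p].to_numpy()) for p in probesets}, name="iqr", dtype=float
    )
    table = pd.DataFrame({"entrez": entrez, "iqr": iqr}).sort_index()
    rows = []
    for gene, grp in table.groupby("entrez", sort=True):
        # stable sort on the index-sorted table makes max-IQR ties resolve
        # to the smallest probeset ID
        best = grp["iqr"].idxmax()
        rows.append(
            {
                "entrez": gene,
                "probeset": best,
                "iqr": grp.loc[best, "iqr"],
                "n_probesets": len(grp),
            }
        )
    report = pd.DataFrame(rows).set_index("entrez")
    gene_mat = mat.loc[report["probeset"]].copy()
    gene_mat.index = report.index
    return gene_mat, report


def spearman_matrix(
    cov: SampleCovariates, variables: list[str]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Spearman rank correlations among sample covariates.

    Categorical variables enter as integer category codes (binary factors
    such as gender become 0/1).  Ties are handled by midranks and p-values
    use the large-sample t approximation.  Constant variables yield NaN
    (undefined correlation), never 0.

    Returns the correlation matrix and the matrix of two-sided p-values.
    """
    if len(cov) < 3:
        raise ValueError("need at least 3 samples for rank correlation")
    data = {}
    for var in variables:
        series = cov[var]
        if cov.type_of(var) == "categorical":
            codes = pd.Categorical(series).codes
            if len(np.unique(codes)) > 2:
                warnings.warn(
                    f"multi-level categorical {var!r} entered as integer codes",
                    stacklevel=2,
                )
            data[var] = codes.astype(float)
        else:
            data[var] = series.to_numpy(float)
    frame = pd.DataFrame(data, index=cov.sample_ids)

    k = len(variables)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            x, y = frame.iloc[:, i], frame.iloc[:, j]
            if x.nunique() < 2 or y.nunique() < 2:
                r, p = np.nan, np.nan
            else:
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore")
                    r, p = stats.spearmanr(x, y)
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    for i in range(k):
        if frame.iloc[:, i].nunique() < 2:
            rho[i, i] = np.nan
            pval[i, i] = np.nan
    rho_df = pd.DataFrame(rho, index=variables, columns=variables)
    p_df = pd.DataFrame(pval, index=variables, columns=variables)
    return rho_df, p_df
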