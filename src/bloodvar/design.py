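"""Design-matrix construction from sample covariates.

A :class:`VariableModel` names the variable(s) of interest and any
confounders.  Continuous covariates are standardized (mean 0, sd 1);
categorical covariates are one-hot encoded dropping the first (sorted)
level, so a k-level factor spends k-1 columns.  An intercept column is
always included; the model's degrees of freedom ``df1`` equal the number of
design columns including the intercept.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import linalg

from .containers import SampleCovariates


class DesignError(ValueError):
    """Raised for invalid or rank-deficient design specifications."""


def _as_tuple(v) -> tuple[str, ...]:
    if isinstance(v, str):
        return (v,)
    return tuple(v)


@dataclass(frozen=True)
class VariableModel:
    """Variable(s) of interest plus confounders for a linear model."""

    variable: str | Sequence[str]
    confounders: Sequence[str] = ()

    def __post_init__(self):
        variables = _as_tuple(self.variable)
        confounders = _as_tuple(self.confounders)
        dup = set(variables) & set(confounders)
        if dup:
            raise DesignError(f"variable(s) duplicated among confounders: {sorted(dup)}")
        if len(set(variables)) != len(variables):
            raise DesignError("duplicated variable of interest")

    @property
    def variables(self) -> tuple[str, ...]:
        return _as_tuple(self.variable)

    @property
    def all_terms(self) -> tuple[str, ...]:
        return self.variables + _as_tuple(self.confounders)


def encode_variable(cov: SampleCovariates, var: str) -> pd.DataFrame:
    """Encode one covariate as design columns (no intercept)."""
    series = cov[var]
    if cov.type_of(var) == "categorical":
        dummies = pd.get_dummies(
            pd.Categorical(series), prefix=var, dtype=float
        ).iloc[:, 1:]
        dummies.index = cov.sample_ids
        if dummies.shape[1] == 0:
            raise DesignError(f"categorical covariate {var!r} has a single level")
        return dummies
    x = series.to_numpy(float)
    sd = x.std(ddof=1)
    if sd == 0:
        raise DesignError(f"continuous covariate {var!r} is constant")
    return pd.DataFrame({var: (x - x.mean()) / sd}, index=cov.sample_ids)


def build_design(model: VariableModel, cov: SampleCovariates) -> pd.DataFrame:
    """Full design matrix: intercept, variable columns, confounder columns.

    Raises :class:`DesignError` naming the collinear columns if the result
    is rank deficient.
    """
    blocks = [pd.DataFrame({"intercept": np.ones(len(cov))}, index=cov.sample_ids)]
    for term in model.all_terms:
        blocks.append(encode_variable(cov, term))
    design = pd.concat(blocks, axis=1)
    X = design.to_numpy(float)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, R, piv = linalg.qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        bad = [design.columns[piv[i]] for i in range(len(diag)) if diag[i] < 1e-10 * diag[0]]
        bad += [design.columns[p] for p in piv[len(diag):]]
        raise DesignError(f"design matrix is rank deficient; collinear columns: {bad}")
    return design


def variable_columns(model: VariableModel, design: pd.DataFrame) -> list[str]:
    """Design columns belonging to the variable(s) of interest."""
    cols = []
    for var in model.variables:
        cols.extend(
            c for c in design.columns if c == var or c.startswith(f"{var}_")
        )
    return cols
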