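"""Shared in-memory containers.

Expression matrices are plain :class:`pandas.DataFrame` objects with feature
identifiers (probesets or Entrez gene IDs) on the rows and sample identifiers
on the columns, holding log2 intensities.  Sample covariates get a light
wrapper that carries the per-variable type declaration (continuous vs
categorical) needed by design-matrix construction and by the rank-correlation
summary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

#: Variables treated as categorical unless declared otherwise.
DEFAULT_CATEGORICAL = ("gender", "donor", "series")


@dataclass
class SampleCovariates:
    """Per-sample covariate table with declared variable types.

    ``data`` is indexed by sample ID, one column per variable.  ``types``
    maps variable name to ``"continuous"`` or ``"categorical"``; variables
    absent from the map default to continuous if numeric, categorical
    otherwise.
    """

    data: pd.DataFrame
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate sample IDs in covariate table: {dups}")
        for var in self.data.columns:
            if var not in self.types:
                if var in DEFAULT_CATEGORICAL or not pd.api.types.is_numeric_dtype(
                    self.data[var]
                ):
                    self.types[var] = "categorical"
                else:
                    self.types[var] = "continuous"

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)

    def type_of(self, variable: str) -> str:
        if variable not in self.types:
            raise KeyError(f"unknown covariate {variable!r}")
        return self.types[variable]

    def __getitem__(self, variable: str) -> pd.Series:
        if variable not in self.data.columns:
            raise KeyError(f"unknown covariate {variable!r}")
        return self.data[variable]

    def to_tsv(self, path) -> None:
        self.data.to_csv(path, sep="\t", index_label="sample_id")

    @classmethod
    def from_tsv(cls, path, types: dict[str, str] | None = None) -> "SampleCovariates":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        return cls(df, dict(types) if types else {})
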