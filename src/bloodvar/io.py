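"""Readers and writers for the tab-separated interchange formats.

Expression tables are features x samples with the feature identifier in the
first column and sample IDs in the header.  Annotation tables map probeset
IDs to Entrez gene IDs and symbols (empty string = unannotated).  Gene sets
use the standard GMT format.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class ParseError(ValueError):
    """Raised when an input table violates the format contract."""


def read_expression(path) -> pd.DataFrame:
    """Read a features x samples log2 expression TSV.

    Rejects duplicate feature IDs, non-numeric cells and ragged rows, naming
    the offending line in the error message.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    except pd.errors.ParserError as exc:
        raise ParseError(f"{path}: malformed table ({exc})") from exc
    if df.columns.duplicated().any():
        dups = df.columns[df.columns.duplicated()].tolist()
        raise ParseError(f"{path}: duplicate sample IDs {dups}")
    if df.index.duplicated().any():
        pos = int(np.flatnonzero(df.index.duplicated())[0])
        raise ParseError(
            f"{path}: duplicate feature ID {df.index[pos]!r} (line {pos + 2})"
        )
    values = np.empty(df.shape, dtype=float)
    for j, col in enumerate(df.columns):
        try:
            values[:, j] = pd.to_numeric(df[col], errors="raise")
        except (ValueError, TypeError):
            bad = pd.to_numeric(df[col], errors="coerce")
            row = int(np.flatnonzero(bad.isna() & df[col].notna())[0])
            raise ParseError(
                f"{path}: non-numeric value {df[col].iloc[row]!r} for feature "
                f"{df.index[row]!r} (line {row + 2}, column {col!r})"
            ) from None
    if not np.isfinite(values).all():
        i, j = map(int, np.argwhere(~np.isfinite(values))[0])
        raise ParseError(
            f"{path}: non-finite value for feature {df.index[i]!r} "
            f"(line {i + 2}, column {df.columns[j]!r})"
        )
    out = pd.DataFrame(values, index=df.index.astype(str), columns=df.columns)
    return out


def write_expression(df: pd.DataFrame, path, index_label: str = "feature_id") -> None:
    df.to_csv(path, sep="\t", index_label=index_label)


def read_annotation(path) -> pd.DataFrame:
    """Read a probeset annotation TSV with columns probeset, entrez, symbol.

    Empty strings in ``entrez``/``symbol`` denote missing annotation and are
    returned as ``NaN``.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    required = {"probeset", "entrez"}
    if not required.issubset(df.columns):
        raise ParseError(
            f"{path}: annotation needs columns {sorted(required)}, got {list(df.columns)}"
        )
    if "symbol" not in df.columns:
        df["symbol"] = ""
    if df["probeset"].duplicated().any():
        dup = df.loc[df["probeset"].duplicated(), "probeset"].iloc[0]
        raise ParseError(f"{path}: duplicate probeset ID {dup!r} in annotation")
    df = df.set_index("probeset")[["entrez", "symbol"]]
    df = df.replace("", np.nan)
    return df


def read_gmt(path) -> dict[str, list[str]]:
    """Read gene sets from a GMT file as a name -> members mapping."""
    from gseapy.parser import read_gmt as _read_gmt  # heavy import, keep lazy

    return _read_gmt(str(path))


def read_gene_list(path) -> list[str]:
    """One gene ID per line; blank lines ignored."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]
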