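"""Offline gene-set over-representation by the hypergeometric test.

Given a selected gene list, a GMT collection and a background universe, each
set's overlap with the list is scored by the upper-tail hypergeometric
probability (Fisher's one-sided test), with Benjamini-Hochberg correction
across sets.  The optional EASE variant discounts the overlap by one gene,
giving a more conservative score for small overlaps.
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy import stats

from .genewise import bh_fdr


def overrepresentation(
    genes: Iterable[str],
    gene_sets: Mapping[str, Iterable[str]],
    background: Iterable[str],
    ease: bool = False,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``genes`` in each gene set.

    Parameters
    ----------
    genes:
        Selected gene list; must be a subset of ``background``.
    gene_sets:
        Mapping set name -> members; members are intersected with the
        background before testing.
    background:
        The gene universe (for expression screens, all genes tested).
    ease:
        If True, apply the EASE correction (overlap reduced by one).

    Returns a frame ordered by p-value with columns ``set_size``,
    ``overlap``, ``pvalue``, ``qvalue`` and ``overlap_genes``.
    """
    bg = set(background)
    if not bg:
        raise ValueError("background gene universe is empty")
    query = set(genes)
    stray = query - bg
    if stray:
        raise ValueError(
            f"{len(stray)} query genes absent from background, e.g. "
            f"{sorted(stray)[:3]}"
        )
    N, n = len(bg), len(query)
    rows = []
    for name, members in gene_sets.items():
        members_bg = set(members) & bg
        K = len(members_bg)
        overlap = sorted(query & members_bg)
        k = len(overlap)
        k_eff = max(k - 1, 0) if ease else k
        if k_eff == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(k_eff - 1, N, K, n))
        rows.append(
            {
                "set": name,
                "set_size": K,
                "overlap": k,
                "pvalue": min(p, 1.0),
                "overlap_genes": ",".join(overlap),
            }
        )
    out = pd.DataFrame(rows).set_index("set")
    if len(out):
        out["qvalue"] = bh_fdr(out["pvalue"].to_numpy())
        out = out.sort_values("pvalue")
        out = out[["set_size", "overlap", "pvalue", "qvalue", "overlap_genes"]]
    return out
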