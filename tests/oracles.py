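"""Independent brute-force oracles used by several test modules."""

import numpy as np
import pandas as pd


def projection_variance_fraction(mat: pd.DataFrame, design: np.ndarray) -> float:
    """Gene-wise brute force for the variance share explained by a design.

    Row-centers the matrix, projects every gene row onto the span of the
    centered design columns (via an explicit hat matrix), and returns the
    ratio of projected to total squared deviation summed over genes:
    ``sum_g ||P x_g||^2 / sum_g ||x_g||^2``.
    """
    X = mat.to_numpy(float)
    Xc = X - X.mean(axis=1, keepdims=True)
    D = np.asarray(design, float)
    Dc = D - D.mean(axis=0, keepdims=True)
    # drop all-zero columns (the intercept vanishes after centering)
    Dc = Dc[:, np.linalg.norm(Dc, axis=0) > 1e-12]
    hat = Dc @ np.linalg.pinv(Dc.T @ Dc) @ Dc.T
    num = sum(float(np.dot(hat @ row, hat @ row)) for row in Xc)
    den = sum(float(np.dot(row, row)) for row in Xc)
    return num / den


def stepup_qvalues(p: np.ndarray) -> np.ndarray:
    """Literal O(m^2) Benjamini-Hochberg step-up definition."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q = np.empty(m)
    for rank_idx, i in enumerate(order):
        candidates = [
            p[order[j]] * m / (j + 1) for j in range(rank_idx, m)
        ]
        q[i] = min(1.0, min(candidates))
    return q
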