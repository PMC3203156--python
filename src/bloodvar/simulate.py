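"""Synthetic blood-transcriptome generator with an exact variance ledger.

The generator mimics the design of a degradation study on whole-blood RNA:
each donor's RNA is split into ``n_series`` aliquots of decreasing integrity
(RIN), and every aliquot is profiled once, giving ``n_donors x n_series``
arrays.  Expression on the log2 scale is built additively from

* a per-gene baseline intensity,
* cell-type marker signatures scaled by each sample's cell proportions,
* per-covariate effect blocks (standardized covariate x per-gene effect),
* a per-gene slope on centered RIN over a degradation-sensitive block,
* Gaussian donor intercepts per gene, and
* i.i.d. Gaussian measurement noise.

All components are retained, so the emitted matrix equals the baseline plus
the component sum bit-for-bit and the realized variance share of every
component can be computed exactly.  Additive mixing on the log2 scale is a
deliberate simplification of physical mRNA mixing: it keeps the variance
ledger exact.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .config import ConfigurationError, SimulationConfig
from .containers import SampleCovariates

_CONTINUOUS_VARS = (
    "age",
    "bmi",
    "leukocyte",
    "lymphocyte_pct",
    "monocyte_pct",
    "neutrophil_pct",
    "erythrocyte",
    "hemoglobin",
    "reticulocyte_pct",
    "platelet",
    "rin",
)


def _stream(config: SimulationConfig, kind: int, name: str) -> np.random.Generator:
    # crc32 keys the substream by variable name so adding or reordering
    # blocks never perturbs the draws of other components.
    return np.random.default_rng(
        [config.seed, 5, kind, zlib.crc32(name.encode()) % (2**31)]
    )


def _decorrelate_by_rank(values: np.ndarray, others: np.ndarray) -> np.ndarray:
    """Re-assign ``values`` across units to suppress correlation with ``others``.

    The sorted values are re-ordered by the ranks of the residual of the
    original draw after least-squares regression on ``others`` (plus
    intercept), which preserves the marginal sample exactly while driving
    the sample correlations with the regressors toward zero.  Skipped when
    there are too few units to leave residual degrees of freedom.
    """
    n, p = len(values), others.shape[1]
    if n < p + 3:
        return values
    X = np.column_stack([np.ones(n), others])
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    resid = values - X @ coef
    out = np.empty(n)
    out[np.argsort(resid, kind="mergesort")] = np.sort(values)
    return out


def simulate_covariates(config: SimulationConfig) -> SampleCovariates:
    """Draw a per-sample covariate table for the configured design.

    Donor-level variables (age, gender, BMI, blood counts) are constant
    across a donor's degradation series; RIN varies per sample around the
    configured series means.  Genders are balanced across donors; lymphocyte
    and neutrophil percentages are strongly anticorrelated because, with
    monocytes and a small remainder, they partition the leukocyte total.
    """
    config.validate()
    rng = config.rng("covariates")
    n_d, n_s = config.n_donors, config.n_series

    genders = np.array(["M"] * (n_d // 2) + ["F"] * (n_d - n_d // 2))
    genders = genders[rng.permutation(n_d)]

    age_values = rng.uniform(22.0, 35.0, size=n_d)
    bmi = np.where(
        genders == "M",
        rng.normal(23.6, 4.0, size=n_d),
        rng.normal(19.0, 1.1, size=n_d),
    ).clip(16.0, 35.0)

    gender01 = (genders == "M").astype(float).reshape(-1, 1)
    # White-cell percentages other than monocyte% are not gender-linked in
    # the blood panel being emulated; suppress the chance correlation of the
    # dominant neutrophil (and hence lymphocyte) draw with gender.
    neutrophil = _decorrelate_by_rank(
        rng.normal(60.5, 7.0, size=n_d).clip(35.0, 80.0), gender01
    )
    monocyte = rng.normal(6.4, 1.2, size=n_d).clip(2.0, 12.0)
    other = rng.normal(2.5, 0.8, size=n_d).clip(0.5, 6.0)  # eosinophils+basophils
    lymphocyte = 100.0 - neutrophil - monocyte - other

    leukocyte = rng.normal(6.2, 2.0, size=n_d).clip(3.0, 12.0)
    erythrocyte = np.where(
        genders == "M", rng.normal(5.5, 0.4, n_d), rng.normal(4.3, 0.3, n_d)
    )
    hemoglobin = np.where(
        genders == "M", rng.normal(162.5, 11.1, n_d), rng.normal(129.8, 8.5, n_d)
    )
    reticulocyte = rng.normal(0.5, 0.3, size=n_d).clip(0.1, 1.5)
    platelet = rng.normal(246.8, 41.3, size=n_d).clip(150.0, 350.0)

    # Age is uncorrelated with every other covariate in the blood panel this
    # generator emulates.  Independent draws leave sizeable chance
    # correlations at cohort sizes of 8-16 donors, so the uniform age values
    # are re-assigned to donors by residual-rank matching: ranks of the age
    # draw after regressing out the other donor-level covariates.  The
    # marginal distribution is untouched.
    age = _decorrelate_by_rank(
        age_values,
        np.column_stack([gender01[:, 0], bmi, lymphocyte, monocyte, neutrophil]),
    )

    rows = []
    for s in range(n_s):
        rin = (
            config.rin_series_means[s] + rng.normal(0.0, config.rin_sd, size=n_d)
        ).clip(0.0, 10.0)
        for d in range(n_d):
            rows.append(
                {
                    "sample_id": f"D{d + 1:02d}_S{s + 1}",
                    "donor": f"D{d + 1:02d}",
                    "series": f"Series_{s + 1}",
                    "gender": genders[d],
                    "age": age[d],
                    "bmi": bmi[d],
                    "leukocyte": leukocyte[d],
                    "lymphocyte_pct": lymphocyte[d],
                    "monocyte_pct": monocyte[d],
                    "neutrophil_pct": neutrophil[d],
                    "erythrocyte": erythrocyte[d],
                    "hemoglobin": hemoglobin[d],
                    "reticulocyte_pct": reticulocyte[d],
                    "platelet": platelet[d],
                    "rin": rin[d],
                }
            )
    df = pd.DataFrame(rows).set_index("sample_id")
    types = {v: "continuous" for v in _CONTINUOUS_VARS}
    types.update({"gender": "categorical", "donor": "categorical", "series": "categorical"})
    return SampleCovariates(df, types)


@dataclass
class SyntheticTruth:
    """Exact decomposition of a simulated expression matrix.

    ``baseline + sum(components.values())`` reproduces the emitted matrix
    exactly; ``block_genes`` records which genes each effect touches.
    """

    baseline: pd.Series
    components: dict[str, pd.DataFrame]
    block_genes: dict[str, list[str]]
    config: SimulationConfig
    seed: int

    def reconstruct(self) -> pd.DataFrame:
        total = sum(self.components.values())
        return total.add(self.baseline, axis=0)

    @property
    def target_fraction(self) -> dict[str, float]:
        return {name: truth_variance_fraction(self, name) for name in self.components}

    def ledger(self) -> dict:
        return {
            "seed": self.seed,
            "variance_fraction": self.target_fraction,
            "block_sizes": {k: len(v) for k, v in self.block_genes.items()},
            "config": _jsonable(self.config.to_dict()),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def _standardize(x: np.ndarray, name: str) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0:
        raise ConfigurationError(f"covariate {name!r} is constant; cannot standardize")
    return (x - x.mean()) / sd


def simulate_expression(
    covariates: SampleCovariates, config: SimulationConfig
) -> tuple[pd.DataFrame, SyntheticTruth]:
    """Emit a log2 expression matrix plus its exact component decomposition."""
    config.validate()
    n = config.n_samples
    if len(covariates) != n:
        raise ConfigurationError(
            f"covariate table has {len(covariates)} rows, expected {n}"
        )
    m = config.n_genes
    gene_ids = [f"G{i + 1:05d}" for i in range(m)]
    sample_ids = covariates.sample_ids

    mu = config.baseline_mean + config.baseline_sd * config.rng("baseline").standard_normal(m)

    components: dict[str, np.ndarray] = {}
    block_genes: dict[str, list[str]] = {}

    def add(name: str, contrib: np.ndarray, idx: np.ndarray) -> None:
        comp = components.setdefault(name, np.zeros((m, n)))
        comp += contrib
        seen = block_genes.setdefault(name, [])
        seen.extend(gene_ids[i] for i in idx if gene_ids[i] not in seen)

    for ct in config.cell_types:
        if ct.variable not in covariates.variables:
            raise ConfigurationError(f"unknown cell-proportion variable {ct.variable!r}")
        if ct.n_genes == 0 or ct.scale == 0:
            components.setdefault("cell_mixture", np.zeros((m, n)))
            continue
        rng = _stream(config, 0, ct.variable)
        idx = rng.choice(m, size=ct.n_genes, replace=False)
        sig = rng.normal(0.0, ct.scale, size=ct.n_genes)
        z = _standardize(covariates[ct.variable].to_numpy(float), ct.variable)
        contrib = np.zeros((m, n))
        contrib[idx] = np.outer(sig, z)
        add("cell_mixture", contrib, idx)

    for block in config.effect_blocks:
        if block.variable not in covariates.variables:
            raise ConfigurationError(f"unknown effect variable {block.variable!r}")
        rng = _stream(config, 1, block.variable)
        contrib = np.zeros((m, n))
        idx = np.array([], dtype=int)
        if block.n_genes > 0 and block.scale > 0:
            idx = rng.choice(m, size=block.n_genes, replace=False)
            beta = rng.normal(0.0, block.scale, size=block.n_genes)
            raw = covariates[block.variable]
            if covariates.type_of(block.variable) == "categorical":
                codes = pd.Categorical(raw).codes.astype(float)
                z = _standardize(codes, block.variable)
            elif block.variable == "rin":
                # centered, not standardized: slope has units log2 per RIN unit
                x = raw.to_numpy(float)
                z = x - x.mean()
            else:
                z = _standardize(raw.to_numpy(float), block.variable)
            contrib[idx] = np.outer(beta, z)
        add(block.variable, contrib, idx)

    donor_codes = pd.Categorical(covariates["donor"]).codes
    u = config.donor_sd * config.rng("donor").standard_normal((m, config.n_donors))
    components["donor"] = u[:, donor_codes]
    block_genes["donor"] = []

    components["noise"] = config.noise_sd * config.rng("noise").standard_normal((m, n))
    block_genes["noise"] = []

    comp_frames = {
        name: pd.DataFrame(mat, index=gene_ids, columns=sample_ids)
        for name, mat in components.items()
    }
    truth = SyntheticTruth(
        baseline=pd.Series(mu, index=gene_ids),
        components=comp_frames,
        block_genes=block_genes,
        config=config,
        seed=config.seed,
    )
    expr = truth.reconstruct()
    return expr, truth


def truth_variance_fraction(truth: SyntheticTruth, variable: str) -> float:
    """Realized share of total across-sample variance held by one component.

    Computed as ``sum_g var_i(component_gi) / sum_g var_i(X_gi)`` with
    variances taken across samples (the same per-gene centering the PCA
    stage uses).  Cross-covariances between components mean the shares need
    not sum to exactly 1.
    """
    if variable not in truth.components:
        raise KeyError(
            f"no stored component {variable!r}; have {sorted(truth.components)}"
        )
    comp = truth.components[variable].to_numpy()
    total = truth.reconstruct().to_numpy()
    denom = total.var(axis=1, ddof=1).sum()
    if denom == 0:
        raise ValueError("emitted matrix has zero total variance")
    return float(comp.var(axis=1, ddof=1).sum() / denom)


def write_simulation(
    out_dir,
    expr: pd.DataFrame,
    covariates: SampleCovariates,
    truth: SyntheticTruth,
    write_components: bool = False,
) -> None:
    """Write ``expr.tsv``, ``covariates.tsv`` and ``truth.json`` to a directory."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    expr.to_csv(out / "expr.tsv", sep="\t", index_label="gene_id")
    covariates.to_tsv(out / "covariates.tsv")
    with open(out / "truth.json", "w") as fh:
        json.dump(truth.ledger(), fh, indent=2)
    if write_components:
        for name, comp in truth.components.items():
            comp.to_csv(out / f"component_{name}.tsv", sep="\t", index_label="gene_id")
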