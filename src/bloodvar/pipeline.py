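"""End-to-end orchestration: ingest, collapse, PCA, Eigen-R2 panel,
gene-wise screening, clustering and a machine-readable report.

Variables in the panel are analysed independently (each with its own
confounder list), mirroring how variance dissection is reported in practice:
one adjusted eigen-R2 and one FDR-gated gene list per variable.  A joint
multi-variable decomposition is available through
:func:`bloodvar.eigenr2.eigen_r2` with a multi-variable model but is not
part of the default panel.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from ._version import __version__
from .collapse import collapse_by_iqr, spearman_matrix
from .cluster import donor_purity, hclust_samples
from .containers import SampleCovariates
from .design import VariableModel
from .eigenr2 import partial_eigen_r2
from .enrich import overrepresentation
from .genewise import fit_genewise, select_genes
from .io import read_annotation, read_expression, read_gmt
from .pca import pca

logger = logging.getLogger("bloodvar")

#: Default confounder lists: gender is included for BMI and the red-cell
#: measures, which differ systematically between men and women.
DEFAULT_CONFOUNDERS = {
    "bmi": ("gender",),
    "erythrocyte": ("gender",),
    "hemoglobin": ("gender",),
    "reticulocyte_pct": ("gender",),
}

DEFAULT_PANEL = (
    "age",
    "gender",
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

CELL_COUNT_VARIABLES = (
    "leukocyte",
    "lymphocyte_pct",
    "monocyte_pct",
    "neutrophil_pct",
)


class PipelineError(RuntimeError):
    """A stage failure, tagged with the stage name."""


@dataclass
class PipelineConfig:
    expression: str
    covariates: str
    out_dir: str
    annotation: str | None = None
    gmt: str | None = None
    variables: list[dict] = field(default_factory=list)
    fdr: float = 0.01
    moderate: bool = True
    cluster_label: str = "donor"
    cluster_k: int | None = None
    cluster_variables: list[str] = field(default_factory=lambda: list(CELL_COUNT_VARIABLES))
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.fdr <= 1:
            raise ValueError(f"fdr threshold must lie in (0, 1], got {self.fdr}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls(**yaml.safe_load(fh))

    def panel(self, available: list[str]) -> list[tuple[str, tuple[str, ...]]]:
        if self.variables:
            out = []
            for spec in self.variables:
                name = spec["name"] if isinstance(spec, dict) else spec
                conf = tuple(spec.get("confounders", ())) if isinstance(spec, dict) else ()
                if name not in available:
                    raise PipelineError(f"[panel] variable {name!r} not in covariate table")
                out.append((name, conf))
            return out
        return [
            (v, DEFAULT_CONFOUNDERS.get(v, ()))
            for v in DEFAULT_PANEL
            if v in available
        ]

    def digest(self) -> str:
        # output location excluded: the hash identifies the analysis, and two
        # runs of one config into different directories must stay identical
        payload = {k: v for k, v in self.__dict__.items() if k != "out_dir"}
        blob = json.dumps(payload, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


REPORT_SCHEMA = {
    "required": {
        "provenance": dict,
        "n_genes": int,
        "n_samples": int,
        "pca": dict,
        "eigen_r2": list,
        "clustering": (dict, type(None)),
    },
    "eigen_r2_entry": {
        "variable": str,
        "confounders": list,
        "raw": float,
        "adjusted": float,
        "adjusted_pct": float,
        "df1": int,
        "n_significant_genes": int,
    },
}


def validate_report(report: dict) -> None:
    """Check the pipeline report against the bundled schema (raises on failure)."""
    for key, typ in REPORT_SCHEMA["required"].items():
        if key not in report:
            raise ValueError(f"report missing key {key!r}")
        if not isinstance(report[key], typ):
            raise ValueError(f"report key {key!r} has type {type(report[key]).__name__}")
    for entry in report["eigen_r2"]:
        for key, typ in REPORT_SCHEMA["eigen_r2_entry"].items():
            if key not in entry:
                raise ValueError(f"eigen_r2 entry missing {key!r}")
            if not isinstance(entry[key], typ):
                raise ValueError(f"eigen_r2 entry key {key!r} has wrong type")


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise PipelineError(f"[{name}] {exc}") from exc
            logger.info("stage %s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return inner

    return wrap


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full analysis and write the report plus tables to ``out_dir``."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    expr = _stage("ingest")(read_expression)(config.expression)
    cov = _stage("ingest")(SampleCovariates.from_tsv)(config.covariates)

    if config.annotation is not None:
        annot = _stage("collapse")(read_annotation)(config.annotation)
        expr, report_tbl = _stage("collapse")(collapse_by_iqr)(expr, annot)
        report_tbl.to_csv(out / "collapse_report.tsv", sep="\t")
        expr.to_csv(out / "gene_expr.tsv", sep="\t", index_label="entrez")

    if list(expr.columns) != list(cov.sample_ids):
        if set(expr.columns) == set(cov.sample_ids):
            cov = SampleCovariates(cov.data.loc[list(expr.columns)], cov.types)
        else:
            raise PipelineError(
                "[ingest] expression and covariate tables list different samples"
            )

    numeric_vars = [
        v
        for v in cov.variables
        if cov.type_of(v) == "continuous"
        or (v == "gender")
    ]
    rho, pvals = _stage("covcorr")(spearman_matrix)(cov, numeric_vars)
    rho.to_csv(out / "covariate_spearman.tsv", sep="\t")
    pvals.to_csv(out / "covariate_spearman_pvalues.tsv", sep="\t")

    dec = _stage("pca")(pca)(expr)
    dec.components_frame().to_csv(out / "pca_components.tsv", sep="\t", index_label="sample_id")
    dec.variance_table().to_csv(out / "pca_variance.tsv", sep="\t")

    panel = config.panel(cov.variables)
    eigen_rows = []
    selected: dict[str, list[str]] = {}
    for variable, confounders in panel:
        part = _stage("eigenr2")(partial_eigen_r2)(dec, variable, confounders, cov)
        res = _stage("genewise")(fit_genewise)(
            expr, VariableModel(variable, confounders), cov, moderate=config.moderate
        )
        genes = select_genes(res, config.fdr)
        selected[variable] = genes
        res.table.sort_values("pvalue").to_csv(out / f"genewise_{variable}.tsv", sep="\t")
        (out / f"genes_{variable}.txt").write_text("".join(g + "\n" for g in genes))
        eigen_rows.append(
            {
                "variable": variable,
                "confounders": list(confounders),
                "raw": part.full.raw,
                "adjusted": part.fraction,
                "adjusted_pct": round(100.0 * part.fraction, 1),
                "full_model_adjusted": part.full.adjusted,
                "df1": part.full.df1,
                "n_significant_genes": len(genes),
            }
        )
    pd.DataFrame(eigen_rows).to_csv(out / "eigenr2.tsv", sep="\t", index=False)

    cluster_section = None
    cluster_genes = sorted(
        {g for v in config.cluster_variables for g in selected.get(v, [])}
    )
    if cluster_genes and config.cluster_label in cov.variables:
        labels = cov[config.cluster_label]
        k = config.cluster_k or labels.nunique()
        dend = _stage("cluster")(hclust_samples)(expr.loc[cluster_genes])
        purity = _stage("cluster")(donor_purity)(dend, labels, k)
        purity.composition.to_csv(out / "cluster_composition.tsv", sep="\t")
        cluster_section = {
            "n_genes": len(cluster_genes),
            "k": k,
            "label": config.cluster_label,
            "ari": purity.ari,
            "leaf_order": dend.leaf_order,
        }

    if config.gmt is not None:
        sets = _stage("enrich")(read_gmt)(config.gmt)
        background = list(expr.index)
        for variable, genes in selected.items():
            if genes:
                enr = _stage("enrich")(overrepresentation)(genes, sets, background)
                enr.to_csv(out / f"enrichment_{variable}.tsv", sep="\t")

    report = {
        "provenance": {
            "package": "bloodvar",
            "version": __version__,
            "seed": config.seed,
            "config_hash": config.digest(),
        },
        "n_genes": int(expr.shape[0]),
        "n_samples": int(expr.shape[1]),
        "pca": {
            "rank": int(dec.r),
            "variance_proportions": [float(x) for x in dec.p],
            "top10_cumulative": float(dec.p[: min(10, dec.r)].sum()),
        },
        "eigen_r2": eigen_rows,
        "clustering": cluster_section,
    }
    validate_report(report)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return report
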