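# bloodvar

Variance dissection of blood gene-expression matrices with the **Eigen-R²**
statistic.

Whole-blood expression profiles are a mixture signal: what looks like a
treatment or phenotype effect is often driven by the donor's cell-type
composition (lymphocyte, monocyte, neutrophil and red-cell proportions), by
demography (age, gender, BMI), or by technical factors such as RNA
degradation (RIN).  `bloodvar` quantifies how much of the total variance of a
log2 expression matrix each such covariate explains, and identifies the
individual genes behind each share.  It is aimed at analysts of bulk blood
microarray or expression matrices who need to decide which covariates must
be controlled before any downstream comparison.

## The statistic

Let `X` be the genes × samples matrix (m genes, n samples), each gene row
centered across samples, with SVD `X = U D Vᵀ`.  The columns `v_k` of `V`
are the principal components (patterns across samples), and PC k carries a
share

    p_k = d_k² / Σ_j d_j²

of the total variance.  For a covariate `z`, each PC is regressed on `z` by
least squares and its coefficient of determination is

    R²_k = Σ_i (v̂_ki − v̂̄_k)² / Σ_i (v_ki − v̄_k)² .

Because distinct PCs are uncorrelated, the explained shares add, and the
fraction of total expression variance explained by `z` is

    eigen-R² = Σ_k p_k · R²_k ,

which (using all PCs) is identical to the variance-weighted mean of
gene-wise R² values.  Small cohorts inflate R² by chance fitting, so the
reported estimator is the adjusted form

    adjusted = 1 − (1 − eigen-R²) · (n − df0) / (n − df1) ,

with `df0 = 1` (intercept-only null) and `df1` the degrees of freedom of the
covariate model.  For a covariate confounded with another (e.g. BMI with
gender), the partial share is `adjusted(variable + confounders) −
adjusted(confounders)`, floored at zero.

Around the statistic the package provides the full workflow: probeset →
Entrez collapsing by maximal IQR, covariate Spearman summaries, per-gene
linear screening with limma-style empirical-Bayes variance moderation and
Benjamini–Hochberg FDR control, correlation-distance hierarchical clustering
with adjusted-Rand donor-purity scoring, offline hypergeometric gene-set
over-representation, and a synthetic blood-transcriptome generator whose
exact per-component variance ledger makes every stage verifiable.

## Worked example

Generate a study-scale synthetic cohort (9,859 genes; 8 donors × 3
degradation series = 24 arrays) and estimate the gender share:

```sh
$ bloodvar simulate --out-dir sim --seed 11
wrote 9859 genes x 24 samples to sim

$ bloodvar eigenr2 --expr sim/expr.tsv --covariates sim/covariates.tsv \
      --variable gender --out er2.tsv
gender: 6.9% of total variation

$ bloodvar genewise --expr sim/expr.tsv --covariates sim/covariates.tsv \
      --variable gender --fdr 0.01 --out gender_genes.tsv
94 genes at FDR < 0.01
```

The generator's ledger (`sim/truth.json`) records that the gender component
actually contributes 7.5% of the realized variance in this draw, so the
adjusted eigen-R² of 6.9% recovers the truth to within less than one
percentage point; the 94 selected genes come from the 120-gene block the
generator made gender-responsive.  The same subcommands (`collapse`,
`covcorr`, `pca`, `cluster`, `enrich`, `run`) accept any externally
normalized expression TSV — the synthetic and real-data paths are the same
code.

The library surface mirrors the CLI, with sklearn-style estimators for the
fit-shaped stages:

```python
import bloodvar as bv

cfg = bv.study_scale_config(seed=11)
cov = bv.simulate_covariates(cfg)
expr, truth = bv.simulate_expression(cov, cfg)
est = bv.EigenR2(variable="gender").fit(expr.T, cov)
est.adjusted_          # 0.069...
```

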