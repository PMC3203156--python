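# Methods

## Model and estimator

The package treats a log2 expression matrix `X` (m genes × n samples) as a
sum of sample-level patterns: each gene row is centered across samples and
the centered matrix is decomposed by SVD, `X̃ = U D Vᵀ`.  Row-centering puts
the all-ones vector in the null space of `X̃`, so every principal component
`v_k` (column of `V`) has mean zero across samples and at most `n − 1`
components are nonzero.  This centering convention is deliberate: the
downstream R² formula measures deviations of fitted values from the PC
mean, which is only an orthogonal decomposition when the PCs themselves are
mean-free.  No column (sample) centering is applied; per-gene baselines are
the only location parameters removed.  All nonzero-rank components are
retained — truncation would discard variance that the weighting `p_k =
d_k²/Σ d_j²` must account for.

For a covariate model (intercept plus encoded variable and confounders),
each `v_k` is fitted by least squares and the eigenvalue-weighted sum
`Σ_k p_k R²_k` is the raw eigen-R².  With all PCs and least-squares fits
this equals `‖X̃P‖²_F / ‖X̃‖²_F`, where `P` projects onto the centered
design span — the test suite asserts this identity to 1e-10 against an
explicit gene-by-gene hat-matrix oracle, which is the strongest single
check of the implementation.

The small-sample adjustment is the classical adjusted-R² form
`1 − (1 − R²)(n − df0)/(n − df1)`, applied to the aggregated statistic with
a single `(df0, df1)` pair (`df0 = 1`, intercept-only null; `df1` = number
of design columns including the intercept, so a k-level factor spends
`k − 1` degrees of freedom).  Applying the adjustment per-PC instead would
compound the penalty r times; the aggregated form matches how a single
variance share is reported.  The adjusted value can be negative and is
reported as computed.  Confounder attribution is sequential:
`adjusted(full) − adjusted(confounders only)`, floored at zero; the
full-model value is kept alongside so users can choose either convention.

## Degrees-of-freedom and encoding conventions

Continuous covariates are standardized (mean 0, sd 1 with the n−1
denominator); standardization does not change any R² but makes gene-wise
coefficients comparable across covariates.  Categorical covariates are
one-hot encoded dropping the first sorted level.  Rank-deficient designs
are rejected with the collinear columns named (QR with pivoting).  Sample
identity between the decomposition and the covariate table is checked by
ID, not position.

## Probeset collapsing

Probesets without an Entrez annotation are removed; among probesets of one
gene the one with the largest across-sample IQR is kept.  Quantiles use
linear interpolation between order statistics (type 7, numpy's default) —
the convention matters only for exact IQR ties, which are broken toward the
lexicographically smallest probeset ID so the collapse is deterministic.
Probesets absent from the annotation table are dropped with a warning by
default; a strict mode turns this into an error.

## Gene-wise screening

Per-gene OLS on the shared design; the reported coefficient is the
variable-of-interest column.  By default residual variances are moderated:
`s²_g` on `d_g` df is shrunk to `(d0·s0² + d_g·s²_g)/(d0 + d_g)` with
`(d0, s0²)` estimated by method of moments on `log s²_g` (digamma/trigamma
moment matching, Newton inversion of the trigamma function), and the
moderated t is referenced to `d0 + d_g` df.  The implementation reproduces
the limma `lmFit`/`eBayes` hyperparameters and moderated t-statistics to
8+ significant digits on a fixed test matrix (frozen reference values
computed with limma 3.58).  `moderate=False` gives plain OLS t-tests.
BH q-values implement the step-up definition directly and are cross-checked
against statsmodels.

DAVID-style web enrichment is replaced by an offline upper-tail
hypergeometric test against a user-supplied GMT collection, with BH
correction across sets and an optional EASE (overlap − 1) variant.
Term-level p-values are not expected to match DAVID's modified Fisher
scores; the test answers the same over-representation question from
reproducible local inputs.

## Clustering

Sample distance is `1 − Pearson` between gene-centered sample profiles with
average linkage — the common microarray convention.  Centering gene rows
first makes the tree invariant to per-gene additive offsets (baseline
intensity), so only deviation patterns drive the clustering.  Trees are cut
by cluster count (default = number of donors) and scored against donor
labels with the adjusted Rand index; ARI = 1 iff the cut reproduces the
donor partition exactly.

## Synthetic blood-transcriptome generator

The generator emulates a degradation study: each donor's RNA is split into
`n_series` aliquots of decreasing integrity, and every aliquot profiled
once.  On the log2 scale a sample's expression is

    X_gi = μ_g + Σ_c s_gc z̃_ic + Σ_v β_gv z̃_iv + δ_g (RIN_i − R̄IN)
           + u_{g,donor(i)} + ε_gi

with marker signatures `s_gc` tied to cell-proportion covariates, effect
blocks `β_gv` on standardized covariates, a per-gene RIN slope on a
degradation-sensitive block, Gaussian donor intercepts and i.i.d. noise.
Mixing acts additively on the log2 scale — a deliberate simplification of
physical mRNA mixing that makes the variance ledger exact: the emitted
matrix equals the baseline plus the stored component matrices bit-for-bit,
and each component's realized variance share is computed directly from its
stored matrix.  The RIN effect is a linear slope per gene (mirroring
transcripts that decline with degradation) rather than a positional 3'-bias
model.

Covariate marginals follow the blood panel of a small healthy cohort:
balanced genders; age uniform on [22, 35] years; BMI normal with
gender-shifted means (23.6 male / 19.0 female); differential counts with
neutrophil% ≈ N(60.5, 7), monocyte% ≈ N(6.4, 1.2) and lymphocyte% as the
remainder of the leukocyte total, which makes lymphocyte% and neutrophil%
strongly anticorrelated (ρ ≈ −0.95 at large cohorts); red-cell measures
gender-shifted; RIN drawn per series around means (8.9, 7.7, 6.5) with sd
0.4, truncated to [0, 10].  Donor-level variables are constant across a
donor's series.

Two draws are structurally decorrelated to match the covariate correlation
pattern such panels show: age is re-assigned across donors by residual
ranks against gender, BMI and the differential counts (age is not
systematically related to any of them), and the neutrophil draw is likewise
decorrelated from gender (white-cell percentages other than monocyte% are
not gender-linked).  Residual-rank re-assignment permutes the drawn values,
so marginals are preserved exactly.  Without this, chance correlations at
8–16 donors (|r| up to ~0.5) let one component's variance leak into another
variable's eigen-R², which is a property of small confounded cohorts rather
than of the estimator; the decorrelated generator isolates estimator error.

Effect scales are solved analytically from target variance fractions
(`config_from_fractions`): a B-gene block with effect sd τ on a
standardized covariate contributes `B·τ²` expected variance, noise
contributes `m·σ²`, donor intercepts `m·σ_d²·(n − n_series)/(n − 1)`.
Defaults target cell-mixture 0.30, gender 0.09, age 0.08, RIN 0.02, donor
0.08, with noise sd 0.35 log2 units taking the remainder — shares typical
of whole-blood studies where cell composition dominates.  Realized
fractions fluctuate around the targets; all recovery checks compare against
the realized ledger, never the target.

Substreams are keyed by component name (CRC32 of the name under the global
seed), so adding or reordering an effect block never perturbs the draws of
other components, and identical (config, seed) gives bit-identical output.

What the generator does **not** emulate: probe-level intensity physics,
RMA normalization artefacts, non-additive (raw-scale) cell mixing,
positional degradation bias, batch/hybridization-date effects, and
heavy-tailed expression noise.  Passing recovery tests therefore shows the
estimator chain is correct under an additive Gaussian variance model, not
that real accession data will decompose as cleanly.

## Problem sizes and numerical choices

Tests and the acceptance script use 2,000 genes × 48 samples (16 donors ×
3 series) for recovery — large enough that block-level effect-size
sampling noise is a few percent — and 9,859 genes × 24 samples for the
study-scale panel, the shape of the motivating design.  SVD is dense LAPACK
(`gesdd`); singular values below `1e-12 · d_1` are treated as rank-zero and
excluded (their weight is zero regardless).  PC signs follow the
largest-magnitude-entry-positive rule so output is deterministic.
Zero-variance genes are retained (they contribute nothing but keep
indexing stable); zero-variance matrices, PCs, samples and constant
covariates are errors, not silent zeros.  Gene-wise p-values are floored at
the smallest positive normal double.

## Known limitations

- Eigen-R² attributes chance-correlated variance to whichever covariate is
  being tested; with few donors and many covariates, partial (confounded)
  attributions depend on the confounder list the analyst chooses.
- The adjusted estimator corrects for sample-level degrees of freedom; with
  technical replicates per donor, donor-level covariates have fewer
  effective units than n and residual optimism remains.
- The hypergeometric enrichment treats genes as exchangeable and ignores
  correlation between co-expressed genes; its p-values are optimistic for
  clustered signals.
- The collapse step inherits whatever annotation release the user supplies;
  gene counts are dataset-specific, not contracts.
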