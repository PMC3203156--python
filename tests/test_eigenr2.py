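"""Eigen-R2: per-PC regression R2, eigenvalue-weighted aggregation,
small-sample adjustment and confounder-adjusted (partial) form."""

from fractions import Fraction

import numpy as np
import pandas as pd
import pytest

import bloodvar as bv
from bloodvar.design import DesignError
from tests.conftest import random_expression
from tests.oracles import projection_variance_fraction


def _cov_from_frame(df: pd.DataFrame) -> bv.SampleCovariates:
    return bv.SampleCovariates(df)


class TestPcR2:
    def test_pc_regressed_on_itself(self, toy_covariates):
        z = toy_covariates["rin"].to_numpy(float)
        v = (z - z.mean()) / np.linalg.norm(z - z.mean())
        assert bv.pc_r2(v, bv.VariableModel("rin"), toy_covariates) == pytest.approx(1.0)

    def test_orthogonal_covariate_gives_zero(self):
        df = pd.DataFrame({"z": [1.0, -1.0, 1.0, -1.0]}, index=list("abcd"))
        cov = _cov_from_frame(df)
        v = np.array([1.0, 1.0, -1.0, -1.0]) / 2.0
        assert bv.pc_r2(v, bv.VariableModel("z"), cov) == pytest.approx(0.0, abs=1e-12)

    def test_matches_brute_force_normal_equations(self):
        v = np.array([1.0, 2.0, 3.0, 5.0])
        z = np.array([1.0, 2.0, 3.0, 4.0])
        cov = _cov_from_frame(pd.DataFrame({"z": z}, index=list("abcd")))
        # brute-force least squares with intercept
        X = np.column_stack([np.ones(4), z])
        coef = np.linalg.solve(X.T @ X, X.T @ v)
        fitted = X @ coef
        expected = np.sum((fitted - fitted.mean()) ** 2) / np.sum((v - v.mean()) ** 2)
        got = bv.pc_r2(v, bv.VariableModel("z"), cov)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_pc_rejected(self):
        cov = _cov_from_frame(pd.DataFrame({"z": [1.0, 2.0, 3.0, 4.0]}, index=list("abcd")))
        with pytest.raises(ValueError, match="zero variance"):
            bv.pc_r2(np.zeros(4), bv.VariableModel("z"), cov)

    def test_collinear_design_named(self):
        df = pd.DataFrame(
            {"z": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0], "w": [2.0, 4.0, 6.0, 8.0, 10.0, 12.0]},
            index=list("abcdef"),
        )
        cov = _cov_from_frame(df)
        with pytest.raises(DesignError, match="collinear"):
            bv.pc_r2(np.array([1.0, 0, 0, 0, 0, -1.0]), bv.VariableModel(("z", "w")), cov)


class TestEigenR2:
    def test_pc_as_covariate_recovers_its_share(self):
        mat = random_expression(np.random.default_rng(10), 30, 6)
        dec = bv.pca(mat)
        for j in range(1, dec.r + 1):
            df = pd.DataFrame({"z": dec.pc(j)}, index=dec.sample_ids)
            res = bv.eigen_r2(dec, bv.VariableModel("z"), _cov_from_frame(df))
            assert res.raw == pytest.approx(dec.p[j - 1], abs=1e-10)

    def test_saturated_design_explains_everything(self):
        mat = random_expression(np.random.default_rng(11), 20, 6)
        dec = bv.pca(mat)
        df = pd.DataFrame(
            {"grp": list("abcdef")}, index=dec.sample_ids
        )
        res = bv.eigen_r2(dec, bv.VariableModel("grp"), _cov_from_frame(df))
        assert res.df1 == 6
        assert np.allclose(res.pc_r2, 1.0, atol=1e-10)
        assert res.raw == pytest.approx(1.0, abs=1e-10)

    def test_frobenius_projection_identity(self):
        # raw eigen-R2 over all PCs equals the gene-wise projection fraction
        rng = np.random.default_rng(12)
        for _ in range(5):
            m, n = rng.integers(5, 120), rng.integers(4, 24)
            mat = random_expression(rng, int(m), int(n))
            z = rng.normal(size=int(n))
            cov = _cov_from_frame(pd.DataFrame({"z": z}, index=mat.columns))
            dec = bv.pca(mat)
            res = bv.eigen_r2(dec, bv.VariableModel("z"), cov)
            design = np.column_stack([np.ones(int(n)), z])
            assert res.raw == pytest.approx(
                projection_variance_fraction(mat, design), abs=1e-10
            )

    def test_adding_a_covariate_never_decreases_raw(self):
        rng = np.random.default_rng(13)
        mat = random_expression(rng, 40, 12)
        df = pd.DataFrame(
            {"z": rng.normal(size=12), "w": rng.normal(size=12)}, index=mat.columns
        )
        cov = _cov_from_frame(df)
        dec = bv.pca(mat)
        single = bv.eigen_r2(dec, bv.VariableModel("z"), cov)
        joint = bv.eigen_r2(dec, bv.VariableModel(("z", "w")), cov)
        assert joint.raw >= single.raw - 1e-12

    def test_sample_order_mismatch_rejected(self):
        mat = random_expression(np.random.default_rng(14), 10, 5)
        dec = bv.pca(mat)
        df = pd.DataFrame(
            {"z": np.arange(5.0)}, index=list(reversed(mat.columns))
        )
        with pytest.raises(ValueError, match="sample order mismatch"):
            bv.eigen_r2(dec, bv.VariableModel("z"), _cov_from_frame(df))

    def test_permutation_null_covers_pure_noise_variable(self):
        rng = np.random.default_rng(15)
        inside = 0
        for trial in range(5):
            mat = random_expression(rng, 60, 18)
            dec = bv.pca(mat)
            z = rng.normal(size=18)
            cov = _cov_from_frame(pd.DataFrame({"z": z}, index=mat.columns))
            observed = bv.eigen_r2(dec, bv.VariableModel("z"), cov).raw
            null = []
            for _ in range(200):
                zp = rng.permutation(z)
                cov_p = _cov_from_frame(pd.DataFrame({"z": zp}, index=mat.columns))
                null.append(bv.eigen_r2(dec, bv.VariableModel("z"), cov_p).raw)
            null = np.array(null)
            assert null.mean() > 0
            lo, hi = np.percentile(null, [2.5, 97.5])
            inside += lo <= observed <= hi
        assert inside >= 4


class TestAdjustment:
    def test_worked_arithmetic(self):
        expected = float(Fraction(1) - Fraction(1, 2) * Fraction(23, 22))
        assert bv.adjusted_eigen_r2(0.5, n=24, df0=1, df1=2) == pytest.approx(
            expected, abs=1e-12
        )

    def test_perfect_fit_stays_perfect(self):
        assert bv.adjusted_eigen_r2(1.0, n=10, df0=1, df1=4) == pytest.approx(1.0)

    def test_equal_dfs_leave_raw_unchanged(self):
        assert bv.adjusted_eigen_r2(0.37, n=12, df0=3, df1=3) == pytest.approx(0.37)

    def test_adjusted_never_exceeds_raw_and_may_be_negative(self):
        assert bv.adjusted_eigen_r2(0.2, n=10, df0=1, df1=5) < 0.2
        assert bv.adjusted_eigen_r2(0.01, n=6, df0=1, df1=4) < 0

    @pytest.mark.parametrize("n,df0,df1", [(4, 1, 4), (4, 1, 5), (4, 0, 2), (4, 3, 2)])
    def test_invalid_dfs_rejected(self, n, df0, df1):
        with pytest.raises(ValueError):
            bv.adjusted_eigen_r2(0.5, n=n, df0=df0, df1=df1)


class TestPartial:
    def test_no_confounders_equals_adjusted(self, small_sim):
        cov, expr, _ = small_sim
        dec = bv.pca(expr)
        part = bv.partial_eigen_r2(dec, "gender", (), cov)
        direct = bv.eigen_r2(dec, bv.VariableModel("gender"), cov)
        assert part.fraction == pytest.approx(direct.adjusted)
        assert part.reduced is None

    def test_duplicated_confounder_rejected(self, small_sim):
        cov, expr, _ = small_sim
        dec = bv.pca(expr)
        with pytest.raises(DesignError, match="duplicated"):
            bv.partial_eigen_r2(dec, "bmi", ("bmi",), cov)

    def test_confounded_variable_attribution(self):
        # BMI effect correlated with gender: the partial share should track
        # the BMI component, not BMI + gender
        cfg = bv.config_from_fractions(
            n_genes=2000,
            n_donors=16,
            fractions={"cell_mixture": 0.25, "gender": 0.09, "bmi": 0.06, "rin": 0.02},
            seed=21,
        )
        cov = bv.simulate_covariates(cfg)
        expr, truth = bv.simulate_expression(cov, cfg)
        dec = bv.pca(expr)
        part = bv.partial_eigen_r2(dec, "bmi", ("gender",), cov)
        assert part.fraction == pytest.approx(
            bv.truth_variance_fraction(truth, "bmi"), abs=0.05
        )
        assert part.full.adjusted >= part.fraction


class TestEstimator:
    def test_fit_matches_functional_route(self, small_sim):
        cov, expr, _ = small_sim
        est = bv.EigenR2(variable="gender").fit(expr.T, cov)
        dec = bv.pca(expr)
        res = bv.eigen_r2(dec, bv.VariableModel("gender"), cov)
        assert est.raw_ == pytest.approx(res.raw, abs=1e-12)
        assert est.adjusted_ == pytest.approx(res.adjusted, abs=1e-12)
        assert est.score() == est.adjusted_

    def test_params_roundtrip(self):
        est = bv.EigenR2(variable="bmi", confounders=("gender",))
        params = est.get_params()
        assert params["variable"] == "bmi"
        clone = bv.EigenR2(**params)
        assert clone.confounders == ("gender",)
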