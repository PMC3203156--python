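"""Gene-wise linear screening, variance moderation, BH-FDR and enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import bloodvar as bv
from bloodvar.design import DesignError
from bloodvar.genewise import moderate_variances
from tests.oracles import stepup_qvalues


def _cov(df: pd.DataFrame) -> bv.SampleCovariates:
    return bv.SampleCovariates(df)


def _single_covariate(z: np.ndarray) -> bv.SampleCovariates:
    return _cov(pd.DataFrame({"z": z}, index=[f"s{i}" for i in range(len(z))]))


class TestFitGenewise:
    def test_matches_brute_force_normal_equations(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([1.0, 2.0, 3.0, 5.0])
        mat = pd.DataFrame([y], index=["g"], columns=[f"s{i}" for i in range(4)])
        res = bv.fit_genewise(mat, bv.VariableModel("z"), _single_covariate(z), moderate=False)
        zs = (z - z.mean()) / z.std(ddof=1)
        X = np.column_stack([np.ones(4), zs])
        coef = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ coef
        s2 = resid @ resid / 2
        se = np.sqrt(s2 * np.linalg.inv(X.T @ X)[1, 1])
        assert res.table.loc["g", "coef"] == pytest.approx(coef[1], abs=1e-12)
        assert res.table.loc["g", "t"] == pytest.approx(coef[1] / se, abs=1e-10)
        assert res.table.loc["g", "df"] == 2

    def test_perfect_fit_reports_solver_minimum_p(self):
        z = np.array([1.0, 2.0, 3.0, 4.0])
        mat = pd.DataFrame(
            [2 * z + 1, [5.0, 5.1, 4.9, 5.0]], index=["hit", "null"],
            columns=[f"s{i}" for i in range(4)],
        )
        res = bv.fit_genewise(mat, bv.VariableModel("z"), _single_covariate(z), moderate=False)
        # residual is zero up to round-off; p collapses to (near) the floor
        assert np.finfo(float).tiny <= res.table.loc["hit", "pvalue"] < 1e-15

    def test_moderation_matches_limma_reference(self):
        # frozen from limma::eBayes(lmFit(...)) on this exact generated set
        rng = np.random.default_rng(42)
        m, n = 80, 12
        z = rng.normal(size=n)
        beta = np.zeros(m)
        beta[:10] = rng.normal(0, 1.0, 10)
        zs = (z - z.mean()) / z.std(ddof=1)
        y = 6 + np.outer(beta, zs) + rng.normal(
            0, rng.uniform(0.2, 1.0, m)[:, None], (m, n)
        )
        mat = pd.DataFrame(
            y, index=[f"g{i}" for i in range(m)], columns=[f"s{j}" for j in range(n)]
        )
        res = bv.fit_genewise(mat, bv.VariableModel("z"), _single_covariate(z), moderate=True)
        assert res.prior_df == pytest.approx(3.471537499, rel=1e-8)
        assert res.prior_var == pytest.approx(0.2024669135, rel=1e-8)
        expected_t = [1.450410641, 5.711679642, 2.161860332, -5.129808327, 2.181026107]
        expected_p = [0.169826752, 6.234102787e-05, 0.04916247944, 0.0001727963949, 0.04745110686]
        assert np.allclose(res.table["t"].to_numpy()[:5], expected_t, rtol=1e-8)
        assert np.allclose(res.table["pvalue"].to_numpy()[:5], expected_p, rtol=1e-8)

    def test_homogeneous_variances_shrink_fully(self):
        s2 = np.full(50, 0.25)
        s2_post, d0, s0_sq = moderate_variances(s2, df=10.0)
        assert np.isinf(d0)
        assert np.allclose(s2_post, s0_sq)

    def test_posterior_between_gene_and_prior_variance(self):
        rng = np.random.default_rng(3)
        s2 = rng.uniform(0.05, 2.0, 200)
        s2_post, d0, s0_sq = moderate_variances(s2, df=8.0)
        assert 0 < d0 < np.inf
        lo = np.minimum(s2, s0_sq)
        hi = np.maximum(s2, s0_sq)
        assert np.all(s2_post >= lo - 1e-12) and np.all(s2_post <= hi + 1e-12)

    def test_zero_residual_df_rejected(self):
        z = np.array([1.0, 2.0])
        mat = pd.DataFrame([[1.0, 2.0]], index=["g"], columns=["s0", "s1"])
        with pytest.raises(DesignError, match="residual"):
            bv.fit_genewise(mat, bv.VariableModel("z"), _single_covariate(z))

    def test_null_pvalues_roughly_uniform(self):
        rng = np.random.default_rng(8)
        m, n = 800, 24
        mat = pd.DataFrame(
            rng.normal(6, 0.5, (m, n)),
            index=[f"g{i}" for i in range(m)],
            columns=[f"s{j}" for j in range(n)],
        )
        res = bv.fit_genewise(mat, bv.VariableModel("z"), _single_covariate(rng.normal(size=n)))
        assert stats.kstest(res.table["pvalue"], "uniform").pvalue > 0.001


class TestBhFdr:
    def test_worked_examples(self):
        assert bv.bh_fdr([0.03]) == pytest.approx([0.03])
        assert np.allclose(bv.bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)
        assert np.allclose(bv.bh_fdr([0.2, 0.2, 0.2]), [0.2] * 3)

    def test_matches_literal_stepup_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(9)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 40))
            q = bv.bh_fdr(p)
            assert np.allclose(q, stepup_qvalues(p), atol=1e-12)
            assert np.allclose(q, multipletests(p, method="fdr_bh")[1], atol=1e-12)

    def test_monotone_in_p_rank(self):
        p = np.random.default_rng(10).uniform(size=100)
        q = bv.bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-15)

    @pytest.mark.parametrize("bad", [[-0.1], [1.2], [np.nan]])
    def test_invalid_pvalues_rejected(self, bad):
        with pytest.raises(ValueError):
            bv.bh_fdr(bad)


class TestSelectGenes:
    @staticmethod
    def _result(p, genes):
        table = pd.DataFrame({"pvalue": p, "qvalue": bv.bh_fdr(p)}, index=genes)
        table["coef"] = 0.0
        return bv.GenewiseResult(table=table, model=bv.VariableModel("z"), moderated=False)

    def test_threshold_edges(self):
        res = self._result([0.001, 0.5, 0.9], ["a", "b", "c"])
        qmin = res.table["qvalue"].min()
        assert bv.select_genes(res, fdr=qmin * 1.001) == ["a"]
        assert bv.select_genes(res, fdr=1e-6) == []
        with pytest.raises(ValueError):
            bv.select_genes(res, fdr=0.0)

    def test_recovers_known_gender_block(self):
        from bloodvar.config import EffectBlock

        cfg = bv.SimulationConfig(
            n_genes=500, n_donors=12, n_series=2, rin_series_means=(8.9, 6.5),
            effect_blocks=(EffectBlock("gender", 50, 3.0),),
            donor_sd=0.02, noise_sd=0.1, seed=17,
        )
        cov = bv.simulate_covariates(cfg)
        expr, truth = bv.simulate_expression(cov, cfg)
        res = bv.fit_genewise(expr, bv.VariableModel("gender"), cov)
        selected = set(bv.select_genes(res, fdr=0.01))
        block = set(truth.block_genes["gender"])
        sensitivity = len(selected & block) / len(block)
        fdp = len(selected - block) / max(len(selected), 1)
        assert sensitivity >= 0.95
        assert fdp <= 0.05


class TestOverrepresentation:
    BACKGROUND = [f"G{i}" for i in range(20)]

    def test_closed_form_full_overlap(self):
        sets = {"S": self.BACKGROUND[:5]}
        out = bv.overrepresentation(self.BACKGROUND[:5], sets, self.BACKGROUND)
        assert out.loc["S", "pvalue"] == pytest.approx(1.0 / 15504, rel=1e-9)
        assert out.loc["S", "overlap"] == 5

    def test_zero_overlap_and_universe_set(self):
        sets = {"disjoint": self.BACKGROUND[10:15], "all": self.BACKGROUND}
        out = bv.overrepresentation(self.BACKGROUND[:5], sets, self.BACKGROUND)
        assert out.loc["disjoint", "pvalue"] == 1.0
        assert out.loc["all", "pvalue"] == 1.0

    def test_list_order_invariance(self):
        sets = {"S": self.BACKGROUND[:8]}
        a = bv.overrepresentation(self.BACKGROUND[2:7], sets, self.BACKGROUND)
        b = bv.overrepresentation(self.BACKGROUND[6:1:-1], sets, self.BACKGROUND)
        pd.testing.assert_frame_equal(a, b)

    def test_ease_is_more_conservative(self):
        sets = {"S": self.BACKGROUND[:5]}
        plain = bv.overrepresentation(self.BACKGROUND[:5], sets, self.BACKGROUND)
        ease = bv.overrepresentation(self.BACKGROUND[:5], sets, self.BACKGROUND, ease=True)
        assert ease.loc["S", "pvalue"] > plain.loc["S", "pvalue"]

    def test_errors(self):
        with pytest.raises(ValueError, match="empty"):
            bv.overrepresentation(["G1"], {}, [])
        with pytest.raises(ValueError, match="absent from background"):
            bv.overrepresentation(["X999"], {"S": ["G1"]}, self.BACKGROUND)


class TestEstimator:
    def test_fit_exposes_selection(self, small_sim):
        cov, expr, _ = small_sim
        est = bv.GenewiseLinearModel(variable="gender", fdr=0.05).fit(expr.T, cov)
        res = bv.fit_genewise(expr, bv.VariableModel("gender"), cov)
        assert np.allclose(est.pvalues_, res.table["pvalue"])
        assert est.selected_ == bv.select_genes(res, 0.05)
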