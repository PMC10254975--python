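"""Linear-model engine: OLS, moderation, FDR, inflation, PCA."""

import subprocess
import sys

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import methsets as m
from methsets.lm import estimate_prior, moderated_t_from_arrays, results_table


def _random_instance(n_feat=50, n_samp=20, seed=0):
    rng = np.random.default_rng(seed)
    Y = pd.DataFrame(rng.standard_normal((n_feat, n_samp)),
                     index=[f"f{i}" for i in range(n_feat)],
                     columns=[f"s{i}" for i in range(n_samp)])
    X = pd.DataFrame(
        {
            "Intercept": 1.0,
            "exposure": rng.integers(0, 2, n_samp).astype(float),
            "age": rng.normal(40, 5, n_samp),
        },
        index=Y.columns,
    )
    return Y, X


class TestFeatureLM:
    def test_exact_line_has_unit_slope_and_zero_residual(self):
        Y = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"], columns=list("abc"))
        X = pd.DataFrame({"Intercept": 1.0, "x": [0.0, 1.0, 2.0]}, index=list("abc"))
        fit = m.fit_feature_lm(Y, X, "x")
        assert fit.coef["f"] == pytest.approx(1.0, abs=1e-12)
        assert fit.sigma["f"] == pytest.approx(0.0, abs=1e-10)
        assert "f" in fit.zero_variance

    def test_intercept_only_coefficient_is_row_mean(self):
        Y, _ = _random_instance(10, 8, seed=1)
        X = pd.DataFrame({"Intercept": 1.0}, index=Y.columns)
        fit = m.fit_feature_lm(Y, X, "Intercept")
        np.testing.assert_allclose(fit.coef, Y.mean(axis=1), atol=1e-12)

    def test_matches_normal_equations_oracle(self):
        Y, X = _random_instance(50, 20, seed=2)
        fit = m.fit_feature_lm(Y, X, "exposure")
        A = X.to_numpy()
        xtx_inv = np.linalg.inv(A.T @ A)
        j = list(X.columns).index("exposure")
        for i, f in enumerate(Y.index):
            b = xtx_inv @ A.T @ Y.iloc[i].to_numpy()
            resid = Y.iloc[i].to_numpy() - A @ b
            s = np.sqrt(resid @ resid / (20 - 3))
            assert fit.coef[f] == pytest.approx(b[j], abs=1e-10)
            assert fit.se[f] == pytest.approx(s * np.sqrt(xtx_inv[j, j]), abs=1e-10)
        assert fit.df_resid == 17

    def test_features_with_missing_values_dropped_and_reported(self):
        Y, X = _random_instance(10, 8, seed=3)
        Y.iloc[2, 4] = np.nan
        fit = m.fit_feature_lm(Y, X, "exposure")
        assert fit.dropped == ["f2"]
        assert "f2" not in fit.coef.index

    def test_rank_deficient_design_names_collinear_column(self):
        Y, X = _random_instance(5, 10, seed=4)
        X["age_copy"] = X["age"]
        with pytest.raises(m.DesignError, match="age"):
            m.fit_feature_lm(Y, X, "exposure")


class TestModeration:
    def test_zero_prior_df_reproduces_ordinary_t(self):
        Y, X = _random_instance(seed=5)
        fit = m.fit_feature_lm(Y, X, "exposure")
        mod = m.ebayes_moderate(fit, prior_df=0.0, prior_var=1.0)
        ordinary = fit.coef / fit.se
        np.testing.assert_allclose(mod.t, ordinary, atol=1e-12)
        np.testing.assert_allclose(
            mod.p, 2 * stats.t.sf(np.abs(ordinary), fit.df_resid), atol=1e-12
        )

    def test_infinite_prior_df_pins_variance_at_prior(self):
        Y, X = _random_instance(seed=6)
        fit = m.fit_feature_lm(Y, X, "exposure")
        mod = m.ebayes_moderate(fit, prior_df=np.inf, prior_var=0.7)
        assert (mod.s2_post == 0.7).all()

    def test_posterior_variance_between_observed_and_prior(self):
        Y, X = _random_instance(seed=7)
        fit = m.fit_feature_lm(Y, X, "exposure")
        mod = m.ebayes_moderate(fit)
        s2 = fit.sigma**2
        lo = np.minimum(s2, mod.prior_var)
        hi = np.maximum(s2, mod.prior_var)
        assert ((mod.s2_post >= lo - 1e-12) & (mod.s2_post <= hi + 1e-12)).all()

    def test_moderated_t_monotone_in_coefficient(self):
        coefs = np.array([0.1, 0.5, 1.0, 2.0])
        s2 = np.full(4, 0.5)
        _, t, _, _ = moderated_t_from_arrays(coefs, s2, 10, 0.3, 4.0, 0.4)
        assert (np.diff(np.abs(t)) > 0).all()

    def test_identical_variances_give_infinite_prior_df(self):
        d0, s0 = estimate_prior(np.full(50, 0.25), 10)
        assert np.isinf(d0)
        with pytest.raises(ValueError):
            estimate_prior(np.array([0.0]), 10)

    def test_null_pipeline_is_calibrated(self):
        rng = np.random.default_rng(8)
        Y = pd.DataFrame(rng.standard_normal((200, 30)),
                         columns=[f"s{i}" for i in range(30)])
        X = pd.DataFrame(
            {"Intercept": 1.0, "exposure": np.r_[np.ones(15), np.zeros(15)]},
            index=Y.columns,
        )
        mod = m.ebayes_moderate(m.fit_feature_lm(Y, X, "exposure"))
        assert stats.kstest(mod.p, "uniform").pvalue > 0.01
        rate = (mod.p < 0.05).mean()
        half = 1.96 * np.sqrt(0.05 * 0.95 / 200)
        assert 0.05 - half <= rate <= 0.05 + half

    def test_agrees_with_limma_ebayes(self, tmp_path):
        """Independent oracle: the R limma implementation of the same
        moderated t-test on a shared fixture."""
        rng = np.random.default_rng(9)
        Y = pd.DataFrame(rng.standard_normal((100, 12)) * rng.uniform(0.5, 2, (100, 1)),
                         index=[f"f{i}" for i in range(100)],
                         columns=[f"s{i}" for i in range(12)])
        grp = np.r_[np.ones(6), np.zeros(6)]
        X = pd.DataFrame({"Intercept": 1.0, "exposure": grp}, index=Y.columns)
        Y.to_csv(tmp_path / "y.tsv", sep="\t")
        script = tmp_path / "oracle.R"
        script.write_text(
            'suppressMessages(library(limma))\n'
            f'y <- as.matrix(read.delim("{tmp_path}/y.tsv", row.names=1))\n'
            f'design <- cbind(Intercept=1, exposure=c(rep(1,6), rep(0,6)))\n'
            'fit <- eBayes(lmFit(y, design))\n'
            'out <- data.frame(t=fit$t[, "exposure"], p=fit$p.value[, "exposure"],\n'
            '                  d0=fit$df.prior, s02=fit$s2.prior)\n'
            f'write.table(out, "{tmp_path}/out.tsv", sep="\\t", quote=FALSE)\n'
        )
        subprocess.run(["Rscript", str(script)], check=True, capture_output=True)
        ref = pd.read_csv(tmp_path / "out.tsv", sep="\t")
        mod = m.ebayes_moderate(m.fit_feature_lm(Y, X, "exposure"))
        assert mod.prior_df == pytest.approx(ref["d0"].iloc[0], rel=1e-4)
        assert mod.prior_var == pytest.approx(ref["s02"].iloc[0], rel=1e-4)
        np.testing.assert_allclose(mod.t, ref["t"], rtol=1e-4)
        np.testing.assert_allclose(mod.p, ref["p"], rtol=1e-4)


class TestBHFdr:
    def test_hand_worked_examples(self):
        assert m.bh_fdr([0.03]) == pytest.approx([0.03])
        np.testing.assert_allclose(m.bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])
        np.testing.assert_allclose(m.bh_fdr([0.2, 0.2, 0.2]), [0.2, 0.2, 0.2])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            m.bh_fdr([0.5, 1.5])
        with pytest.raises(ValueError):
            m.bh_fdr([-0.1])

    @settings(max_examples=30, derandomize=True)
    @given(st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=1, max_size=60))
    def test_matches_step_up_oracle_and_dominates_p(self, p):
        q = m.bh_fdr(p)
        p = np.asarray(p)
        n = len(p)
        order = np.argsort(p, kind="mergesort")
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        oracle = np.empty(n)
        oracle[order] = np.minimum(adj, 1.0)
        np.testing.assert_allclose(q, oracle, atol=1e-12)
        assert (q >= p - 1e-12).all()


class TestGenomicInflation:
    def test_uniform_quantiles_give_unit_lambda(self):
        p = (np.arange(1, 2001) - 0.5) / 2000
        assert m.genomic_inflation(p) == pytest.approx(1.0, abs=1e-3)

    def test_median_p_gives_unit_lambda(self):
        assert m.genomic_inflation(np.full(11, 0.5)) == pytest.approx(1.0, abs=1e-12)

    def test_zero_pvalue_returns_infinity_with_warning(self):
        with pytest.warns(UserWarning):
            assert np.isinf(m.genomic_inflation([0.0, 0.5]))

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            m.genomic_inflation([])


class TestPCA:
    def test_rank_one_matrix_fully_explained_by_first_component(self):
        u = np.arange(1, 8, dtype=float)[:, None]
        v = np.linspace(-1, 1, 5)[None, :]
        M = pd.DataFrame(u @ v)
        res = m.pca_scores(M, 1)
        assert res.explained_ratio[0] == pytest.approx(1.0, abs=1e-12)

    def test_full_rank_scores_reconstruct_centered_matrix(self):
        rng = np.random.default_rng(10)
        M = pd.DataFrame(rng.standard_normal((30, 8)))
        res = m.pca_scores(M, 7)
        centered = M.to_numpy() - M.to_numpy().mean(axis=1, keepdims=True)
        recon = res.loadings @ res.scores.to_numpy().T
        np.testing.assert_allclose(recon, centered, atol=1e-10)

    def test_scores_are_orthogonal(self):
        rng = np.random.default_rng(11)
        M = pd.DataFrame(rng.standard_normal((40, 12)))
        S = m.pca_scores(M, 5).scores.to_numpy()
        gram = S.T @ S
        off = gram - np.diag(np.diag(gram))
        assert np.abs(off).max() < 1e-8

    def test_sign_convention_is_deterministic(self):
        rng = np.random.default_rng(12)
        M = pd.DataFrame(rng.standard_normal((20, 6)))
        a = m.pca_scores(M, 3).scores
        b = m.pca_scores(M.copy(), 3).scores
        pd.testing.assert_frame_equal(a, b)
        k = np.argmax(np.abs(m.pca_scores(M, 3).loadings[:, 0]))
        assert m.pca_scores(M, 3).loadings[k, 0] > 0

    def test_k_out_of_range_rejected(self):
        M = pd.DataFrame(np.eye(4))
        with pytest.raises(ValueError):
            m.pca_scores(M, 5)


def test_results_table_schema(small_cohort):
    X = m.build_design(small_cohort.covariates,
                       ["exposure", "age", "sex", "bmi", "alcohol", "ses"])
    mod = m.ebayes_moderate(m.fit_feature_lm(small_cohort.beta, X, "exposure"))
    tab = results_table(mod, small_cohort.annotation.to_frame())
    assert {"chrom", "pos", "genes", "coef", "se", "t", "p", "fdr"} <= set(tab.columns)
    assert tab["p"].is_monotonic_increasing
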