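import numpy as np
import pytest

from mtvlmm.design import build_kinship, build_lagged_design, quantile_bin
from mtvlmm.prediction import (
    blup_predict,
    community_cross_cov,
    estimate_associations,
    pca_embedding,
    prediction_r2,
    sequential_predict,
)
from mtvlmm.reml import REMLFit, reml_fit
from mtvlmm.selection import chrono_split
from mtvlmm.synthetic import simulate_lmm


def fitted_instance(seed=1, chi=0.4, ind=0.2, **kw):
    kw.setdefault("n_individuals", 2)
    kw.setdefault("timepoints", 12)
    kw.setdefault("m_taxa", 5)
    ds, truth = simulate_lmm(chi=chi, ind_fraction=ind, seed=seed, **kw)
    d = build_lagged_design(
        ds, truth.community_coding, truth.focal_taxon, p=0, q=1,
        kinship_taxa=truth.kinship_taxa, rng_seed=seed,
    )
    k = build_kinship(d)
    return ds, d, k, reml_fit(d, k), truth


class TestBlupPredict:
    def test_zero_random_effects_collapse_to_fixed_mean(self):
        _, d, k, fit, _ = fitted_instance()
        fit = REMLFit(
            beta=fit.beta, sigma2_AR=0.0, sigma2_ind=0.0, sigma2_eps=0.3,
            vc_cov=np.zeros((3, 3)), loglik_restricted=0.0, converged=True,
            n_iter=1,
        )
        w_new = np.ones(k.m_cols)
        pred = blup_predict(
            fit, d, k, np.ones(1), w_new, np.zeros(d.n)
        )
        assert pred.predicted[0] == pytest.approx(float(fit.beta[0]))
        assert pred.conditional_var[0] == pytest.approx(0.3)

    def test_zero_cross_covariance_gives_marginal(self):
        _, d, k, fit, _ = fitted_instance(seed=2)
        w_new = np.zeros(k.m_cols)
        pred = blup_predict(fit, d, k, np.ones(1), w_new, np.zeros(d.n))
        marginal = fit.sigma2_ind * np.mean(np.diag(k.K2)) + fit.sigma2_eps
        assert pred.predicted[0] == pytest.approx(float(fit.beta[0]))
        assert pred.conditional_var[0] == pytest.approx(marginal)

    def test_matches_joint_gaussian_conditioning(self):
        # explicit (n+1) x (n+1) covariance assembly and partitioning
        rng = np.random.default_rng(3)
        _, d, k, fit, _ = fitted_instance(seed=3)
        w_new = rng.choice([0.0, 1.0, 2.0], size=k.m_cols)
        cc = community_cross_cov(fit, d, k, w_new,
                                 individual=d.row_index[0][0])
        pred = blup_predict(fit, d, k, np.ones(1), w_new, cc)
        n, c = d.n, k.m_cols
        s_u = fit.sigma2_AR / c
        J = np.empty((n + 1, n + 1))
        J[:n, :n] = (
            fit.sigma2_AR * k.K1 + fit.sigma2_ind * k.K2
            + fit.sigma2_eps * np.eye(n)
        )
        J[:n, -1] = J[-1, :n] = cc
        J[-1, -1] = (
            s_u * w_new @ w_new
            + fit.sigma2_ind * np.mean(np.diag(k.K2))
            + fit.sigma2_eps
        )
        resid = d.y - d.X @ fit.beta
        mean_o = fit.beta[0] + J[-1, :n] @ np.linalg.inv(J[:n, :n]) @ resid
        var_o = J[-1, -1] - J[-1, :n] @ np.linalg.inv(J[:n, :n]) @ J[:n, -1]
        assert pred.predicted[0] == pytest.approx(mean_o, abs=1e-8)
        assert pred.conditional_var[0] == pytest.approx(var_o, abs=1e-8)

    def test_conditional_variance_positive(self):
        rng = np.random.default_rng(4)
        for seed in range(4, 8):
            _, d, k, fit, _ = fitted_instance(seed=seed)
            w_new = rng.choice([0.0, 1.0, 2.0], size=k.m_cols)
            cc = community_cross_cov(fit, d, k, w_new,
                                     individual=d.row_index[0][0])
            pred = blup_predict(fit, d, k, np.ones(1), w_new, cc)
            assert pred.conditional_var[0] > 0

    def test_unconverged_fit_rejected(self):
        _, d, k, fit, _ = fitted_instance(seed=5)
        fit.converged = False
        with pytest.raises(ValueError, match="converged"):
            blup_predict(fit, d, k, np.ones(1), np.zeros(k.m_cols),
                         np.zeros(d.n))


class TestSequentialPredict:
    def _recurrence_dataset(self, noise=0.0, T=36, seed=0):
        from conftest import make_series_dataset

        rng = np.random.default_rng(seed)
        series = {}
        for ind in ("A", "B"):
            y = np.empty(T)
            y[0] = 1.0 + 0.1 * rng.standard_normal()
            for t in range(1, T):
                y[t] = 0.5 + 0.8 * y[t - 1] + noise * rng.standard_normal()
            series[ind] = y
        return make_series_dataset(series, m_extra=4, seed=seed)

    def test_noiseless_recurrence_predicted_near_perfectly(self):
        ds = self._recurrence_dataset(noise=0.0)
        split = chrono_split(ds, l_max=1)
        out = sequential_predict(ds, "focal", p=1, q=1, split=split,
                                 rng_seed=0)
        assert prediction_r2(out["observed"], out["predicted"]) >= 0.99

    def test_white_noise_has_no_skill(self):
        from conftest import make_series_dataset

        rng = np.random.default_rng(6)
        ds = make_series_dataset(
            {"A": 2 + rng.standard_normal(40),
             "B": 2 + rng.standard_normal(40)},
            m_extra=4, seed=6,
        )
        split = chrono_split(ds, l_max=1)
        out = sequential_predict(ds, "focal", p=1, q=1, split=split,
                                 rng_seed=0)
        assert prediction_r2(out["observed"], out["predicted"]) < 0.25

    def test_deterministic_reruns(self):
        ds = self._recurrence_dataset(noise=0.2, seed=7)
        split = chrono_split(ds, l_max=1)
        a = sequential_predict(ds, "focal", p=1, q=1, split=split, rng_seed=3)
        b = sequential_predict(ds, "focal", p=1, q=1, split=split, rng_seed=3)
        np.testing.assert_array_equal(a["predicted"], b["predicted"])

    def test_predictions_nonnegative(self):
        ds = self._recurrence_dataset(noise=0.5, seed=8)
        split = chrono_split(ds, l_max=1)
        out = sequential_predict(ds, "focal", p=1, q=1, split=split,
                                 rng_seed=0)
        assert (out["predicted"] >= 0).all()


class TestPredictionR2:
    def test_perfect(self):
        assert prediction_r2([1, 2, 3, 4], [1, 2, 3, 4]) == pytest.approx(1.0)

    def test_affine_invariance(self):
        obs = np.array([0.1, 0.4, 0.2, 0.9])
        assert prediction_r2(obs, 2 * obs + 5) == pytest.approx(1.0)

    def test_hand_computed_example(self):
        # Pearson r = 0.8 for this permutation, so r^2 = 0.64
        assert prediction_r2([1, 2, 3, 4], [1, 3, 2, 4]) == pytest.approx(0.64)

    def test_zero_variance_returns_zero(self):
        assert prediction_r2([1, 1, 1], [1, 2, 3]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            prediction_r2([1, 2, 3], [1, 2])

    def test_too_short(self):
        with pytest.raises(ValueError, match="3 points"):
            prediction_r2([1, 2], [1, 2])


class TestAssociations:
    def test_zero_sigma_u_gives_zero_column(self):
        ds, d, k, fit, _ = fitted_instance(seed=9)
        fit = REMLFit(
            beta=fit.beta, sigma2_AR=0.0, sigma2_ind=0.1, sigma2_eps=0.5,
            vc_cov=np.zeros((3, 3)), loglik_restricted=0.0, converged=True,
            n_iter=1,
        )
        assoc = estimate_associations(ds, {"focal": fit}, {"focal": d})
        jcol = assoc.taxa_ids.index("focal")
        assert np.all(assoc.U[:, jcol] == 0)
        assert "focal" in assoc.column_meta["zero_columns"]

    def test_matches_joint_normal_conditional_expectation(self):
        # E[u | y] for the random-effect vector via explicit joint-normal
        # algebra: Cov(u, y) = s_u W~', so E[u|y] = s_u W~' Sigma^-1 resid
        ds, d, k, fit, _ = fitted_instance(seed=10)
        assoc = estimate_associations(ds, {"focal": fit}, {"focal": d})
        c = k.m_cols
        s_u = fit.sigma2_AR / c
        Sigma = (
            s_u * d.W_tilde @ d.W_tilde.T
            + (fit.sigma2_ind / c) * d.H @ d.H.T
            + fit.sigma2_eps * np.eye(d.n)
        )
        expect = s_u * d.W_tilde.T @ np.linalg.solve(
            Sigma, d.y - d.X @ fit.beta
        )
        jcol = assoc.taxa_ids.index("focal")
        kin_rows = [assoc.taxa_ids.index(t) for t in d.kinship_taxa]
        np.testing.assert_allclose(assoc.U[kin_rows, jcol][:c], expect,
                                   atol=1e-10)

    def test_planted_effects_are_enriched(self):
        # taxa with large true |u| should receive large estimated |u|
        from scipy import stats

        ds, truth = simulate_lmm(n_individuals=10, timepoints=40, m_taxa=12,
                                 chi=0.6, ind_fraction=0.1, seed=11)
        d = build_lagged_design(
            ds, truth.community_coding, truth.focal_taxon, p=0, q=1,
            kinship_taxa=truth.kinship_taxa, rng_seed=11,
        )
        k = build_kinship(d)
        fit = reml_fit(d, k)
        assoc = estimate_associations(ds, {"focal": fit}, {"focal": d})
        jcol = assoc.taxa_ids.index("focal")
        kin_rows = [assoc.taxa_ids.index(t) for t in d.kinship_taxa]
        est = np.abs(assoc.U[kin_rows, jcol])
        rho = stats.spearmanr(est, np.abs(truth.u_true)).statistic
        assert rho > 0.4


class TestPcaEmbedding:
    def test_rank_one_kinship(self):
        v = np.array([1.0, 2.0, 3.0])
        K = np.outer(v, v)
        _, frac = pca_embedding(K, 2)
        assert frac[0] == pytest.approx(1.0)

    def test_identity_kinship_equal_variance(self):
        _, frac = pca_embedding(np.eye(4), 4)
        np.testing.assert_allclose(frac, 0.25)

    def test_matches_dense_eigen_oracle(self):
        rng = np.random.default_rng(12)
        A = rng.standard_normal((4, 4))
        K = A @ A.T
        scores, frac = pca_embedding(K, 4)
        w, Q = np.linalg.eigh(K)
        w, Q = w[::-1], Q[:, ::-1]
        np.testing.assert_allclose(np.abs(scores), np.abs(Q * np.sqrt(w)),
                                   atol=1e-10)
        np.testing.assert_allclose(frac, w / w.sum(), atol=1e-12)

    def test_asymmetric_input_uses_centered_svd(self):
        rng = np.random.default_rng(13)
        U = rng.standard_normal((6, 6))
        scores, frac = pca_embedding(U, 3)
        assert scores.shape == (6, 3)
        assert frac.sum() <= 1.0 + 1e-12
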