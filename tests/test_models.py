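"""Unit and oracle tests for the five whole-genome prediction models."""

import itertools

import numpy as np
import pytest

from wgpkit.genotypes import apply_snp_qc, impute_and_standardize
from wgpkit.models import (
    McmcSettings,
    fit_bayesb,
    fit_elastic_net,
    fit_lasso,
    fit_rkhs,
    fit_rrblup,
    kkt_residual,
    predict,
    predict_rrblup_dual,
)

from .conftest import random_standardized


def enet_bruteforce(Z, y_c, lam, alpha):
    """Exact elastic-net solution by enumerating sign patterns (p <= 8).

    For each candidate sign pattern the stationarity system is solved in
    closed form and the KKT conditions checked; the unique valid pattern
    gives the solution of (1/(2n))||y_c - Zu||^2 + lam(a||u||_1
    + (1-a)/2||u||^2).
    """
    n, p = Z.shape
    best = None
    for signs in itertools.product((-1, 0, 1), repeat=p):
        s = np.array(signs, dtype=float)
        A = np.where(s != 0)[0]
        u = np.zeros(p)
        if A.size:
            ZA = Z[:, A]
            M = ZA.T @ ZA / n + lam * (1 - alpha) * np.eye(A.size)
            rhs = ZA.T @ y_c / n - lam * alpha * s[A]
            uA = np.linalg.solve(M, rhs)
            if not np.all(np.sign(uA) == s[A]):
                continue
            u[A] = uA
        if kkt_residual(Z, y_c, 0.0, u, lam, alpha) < 1e-9:
            obj = (np.sum((y_c - Z @ u) ** 2) / (2 * n)
                   + lam * (alpha * np.abs(u).sum() + (1 - alpha) / 2 * u @ u))
            if best is None or obj < best[0]:
                best = (obj, u)
    assert best is not None, "no sign pattern satisfied the KKT conditions"
    return best[1]


class TestRrblup:
    def test_fixed_lambda_matches_primal_closed_form(self):
        rng = np.random.default_rng(0)
        for p in (5, 50):
            Z = random_standardized(rng, 30, p)
            y = rng.standard_normal(30) + Z.Z @ rng.standard_normal(p) * 0.3
            lam = 7.5
            fit = fit_rrblup(Z, y, lambda_rr=lam)
            u = np.linalg.solve(Z.Z.T @ Z.Z + lam * np.eye(p), Z.Z.T @ (y - fit.mu))
            np.testing.assert_allclose(fit.snp_effects, u, atol=1e-8)

    def test_infinite_shrinkage_gives_mean_prediction(self):
        rng = np.random.default_rng(1)
        Z = random_standardized(rng, 25, 10)
        y = rng.standard_normal(25)
        fit = fit_rrblup(Z, y, lambda_rr=1e12)
        assert np.abs(fit.snp_effects).max() < 1e-6
        np.testing.assert_allclose(predict(fit, Z), fit.mu, atol=1e-4)

    def test_duplicate_columns_equal_effects(self):
        rng = np.random.default_rng(2)
        Z = random_standardized(rng, 30, 6)
        Z.Z[:, 1] = Z.Z[:, 0]
        y = Z.Z @ np.array([1.0, 0, 0.5, 0, 0, -0.3]) + 0.1 * rng.standard_normal(30)
        fit = fit_rrblup(Z, y)
        assert fit.snp_effects[0] == pytest.approx(fit.snp_effects[1], abs=1e-10)

    def test_effect_and_kernel_predictions_agree(self):
        rng = np.random.default_rng(3)
        Z = random_standardized(rng, 40, 30)
        y = Z.Z @ (rng.standard_normal(30) * 0.4) + rng.standard_normal(40)
        fit = fit_rrblup(Z, y)
        new = rng.choice([0.0, 2.0], size=(8, 30))
        via_effects = predict(fit, new)
        via_kernel = predict_rrblup_dual(fit, Z, new)
        np.testing.assert_allclose(via_effects, via_kernel, atol=1e-6)

    def test_training_prediction_equals_blup(self):
        rng = np.random.default_rng(4)
        Z = random_standardized(rng, 30, 20)
        y = rng.standard_normal(30)
        fit = fit_rrblup(Z, y)
        np.testing.assert_allclose(
            predict(fit, Z), fit.mu + fit.genotype_effects, atol=1e-8
        )

    def test_missing_new_line_predicts_mean(self):
        rng = np.random.default_rng(5)
        Z = random_standardized(rng, 30, 12)
        y = rng.standard_normal(30)
        fit = fit_rrblup(Z, y)
        new = np.full((1, 12), np.nan)
        assert predict(fit, new)[0] == pytest.approx(fit.mu, abs=1e-10)

    def test_zero_variance_trait_rejected(self):
        rng = np.random.default_rng(6)
        Z = random_standardized(rng, 20, 5)
        with pytest.raises(ValueError):
            fit_rrblup(Z, np.ones(20))


class TestLasso:
    def test_lambda_max_gives_null_model(self):
        rng = np.random.default_rng(7)
        Z = random_standardized(rng, 30, 8)
        y = rng.standard_normal(30)
        lam_max = np.abs(Z.Z.T @ (y - y.mean())).max() / 30
        fit = fit_lasso(Z, y, fixed_lambda=lam_max * 1.0000001)
        assert np.all(fit.snp_effects == 0.0)

    def test_matches_bruteforce_oracle(self):
        rng = np.random.default_rng(8)
        for rep in range(5):
            Z = random_standardized(rng, 30, 4)
            y = Z.Z @ rng.standard_normal(4) + rng.standard_normal(30)
            y_c = y - y.mean()
            lam = float(np.abs(Z.Z.T @ y_c).max() / 30) * 0.3
            fit = fit_lasso(Z, y, fixed_lambda=lam, tol=1e-12)
            oracle = enet_bruteforce(Z.Z, y_c, lam, 1.0)
            np.testing.assert_allclose(fit.snp_effects, oracle, atol=1e-6)

    def test_kkt_satisfied_after_cv_selection(self):
        rng = np.random.default_rng(9)
        Z = random_standardized(rng, 40, 25)
        y = Z.Z @ np.r_[2.0, np.zeros(24)] + 0.5 * rng.standard_normal(40)
        fit = fit_lasso(Z, y, seed=1, tol=1e-10)
        assert fit.diagnostics["kkt_residual"] < 1e-6
        assert fit.hyperparams["n_nonzero"] < 25

    def test_major_qtl_snp_enters_active_set(self, small_major_qtl):
        panel, trait, truth = small_major_qtl
        pq, _ = apply_snp_qc(panel)
        Z = impute_and_standardize(pq)
        fit = fit_lasso(Z, trait.values, seed=0)
        ids = list(Z.snp_map["snp_id"])
        active = np.where(fit.snp_effects != 0)[0]
        assert active.size > 0
        j_causal = ids.index(truth.qtl_snp_id)
        r2 = max(
            np.corrcoef(Z.Z[:, j_causal], Z.Z[:, a])[0, 1] ** 2 for a in active
        )
        assert r2 > 0.8


class TestElasticNet:
    def test_alpha_one_coincides_with_lasso(self):
        rng = np.random.default_rng(10)
        Z = random_standardized(rng, 30, 10)
        y = rng.standard_normal(30)
        lam = 0.05
        en = fit_elastic_net(Z, y, fixed=(1.0, lam), tol=1e-12)
        la = fit_lasso(Z, y, fixed_lambda=lam, tol=1e-12)
        np.testing.assert_allclose(en.snp_effects, la.snp_effects, atol=1e-8)

    def test_alpha_zero_coincides_with_ridge(self):
        rng = np.random.default_rng(11)
        n, p = 30, 10
        Z = random_standardized(rng, n, p)
        y = rng.standard_normal(n)
        lam = 0.4
        en = fit_elastic_net(Z, y, fixed=(0.0, lam), tol=1e-14)
        ridge = np.linalg.solve(Z.Z.T @ Z.Z + n * lam * np.eye(p),
                                Z.Z.T @ (y - y.mean()))
        np.testing.assert_allclose(en.snp_effects, ridge, atol=1e-6)

    def test_grouping_effect_on_duplicated_column(self):
        rng = np.random.default_rng(12)
        Z = random_standardized(rng, 40, 5)
        Z.Z[:, 1] = Z.Z[:, 0]
        y = Z.Z @ np.array([1.5, 0.0, 0.2, 0.0, 0.0]) + 0.2 * rng.standard_normal(40)
        y_c = y - y.mean()
        lam, alpha = 0.1, 0.5
        fit = fit_elastic_net(Z, y, fixed=(alpha, lam), tol=1e-14)
        assert fit.snp_effects[0] == pytest.approx(fit.snp_effects[1], abs=1e-6)
        oracle = enet_bruteforce(Z.Z, y_c, lam, alpha)
        np.testing.assert_allclose(fit.snp_effects, oracle, atol=1e-6)

    def test_cv_selection_reports_grid_choice(self):
        rng = np.random.default_rng(13)
        Z = random_standardized(rng, 40, 15)
        y = Z.Z @ np.r_[3.0, np.zeros(14)] + 0.3 * rng.standard_normal(40)
        fit = fit_elastic_net(Z, y, alpha_grid=[0.2, 1.0], seed=3)
        assert fit.hyperparams["alpha"] in (0.2, 1.0)
        assert fit.diagnostics["kkt_residual"] < 1e-6


class TestRkhs:
    def _panel(self, seed=14, n=60):
        from .conftest import small_sim_config
        from wgpkit.simulate import simulate_genotypes

        cfg = small_sim_config(n_lines=n, seed=seed)
        panel = simulate_genotypes(cfg)
        panel, _ = apply_snp_qc(panel)
        return panel

    def test_training_fit_interpolates_high_h2(self):
        panel = self._panel()
        rng = np.random.default_rng(0)
        y = rng.standard_normal(panel.n_lines)
        fit = fit_rkhs(panel, y)
        assert 0.1 <= fit.hyperparams["theta"] <= 100.0
        preds = predict(fit, panel)
        np.testing.assert_allclose(preds, fit.mu + fit.genotype_effects, atol=1e-8)

    def test_huge_theta_collapses_to_intercept(self):
        panel = self._panel(seed=15)
        rng = np.random.default_rng(1)
        y = rng.standard_normal(panel.n_lines)
        fit = fit_rkhs(panel, y, theta_grid=[100.0])
        # K ~ constant: genotype effects nearly equal; predictions ~ mean
        assert np.std(fit.genotype_effects) < 0.5 * np.std(y)

    def test_additive_trait_tracks_rrblup(self, small_polygenic):
        panel, trait, _ = small_polygenic
        pq, _ = apply_snp_qc(panel)
        n_train = 90
        train_ids = pq.line_ids[:n_train]
        test_ids = pq.line_ids[n_train:]
        from wgpkit.crossval import _drop_monomorphic, _subset_rows

        tr = _drop_monomorphic(_subset_rows(pq, train_ids))
        te = _subset_rows(pq, test_ids)
        y_tr = trait.values[:n_train]
        y_te = trait.values[n_train:]
        Z = impute_and_standardize(tr)
        r_rr = np.corrcoef(y_te, predict(fit_rrblup(Z, y_tr), te))[0, 1]
        r_k = np.corrcoef(y_te, predict(fit_rkhs(tr, y_tr), te))[0, 1]
        assert abs(r_rr - r_k) < 0.15


class TestBayesB:
    def test_fixed_seed_reproducible(self):
        rng = np.random.default_rng(16)
        Z = random_standardized(rng, 40, 20)
        y = Z.Z @ np.r_[1.0, np.zeros(19)] + 0.3 * rng.standard_normal(40)
        m = McmcSettings(n_iter=400, burn_in=100, thin=2, reduce_to=None, seed=7)
        f1 = fit_bayesb(Z, y, m)
        f2 = fit_bayesb(Z, y, m)
        np.testing.assert_array_equal(f1.snp_effects, f2.snp_effects)
        assert f1.hyperparams == f2.hyperparams

    def test_conjugate_mode_matches_bayesian_ridge(self):
        rng = np.random.default_rng(17)
        n, p = 60, 20
        Z = random_standardized(rng, n, p)
        y = Z.Z @ (0.3 * rng.standard_normal(p)) + rng.standard_normal(n)
        s2u, s2e = 0.09, 1.0
        mu0 = float(y.mean())
        m = McmcSettings(n_iter=4000, burn_in=500, thin=1, reduce_to=None, seed=21,
                         common_effect_variance=s2u, fix_sigma2_e=s2e, fix_mu=mu0)
        fit = fit_bayesb(Z, y, m)
        exact = np.linalg.solve(Z.Z.T @ Z.Z + s2e / s2u * np.eye(p),
                                Z.Z.T @ (y - mu0))
        mcse = fit.diagnostics["posterior_sd"] / np.sqrt(fit.diagnostics["n_samples"] / 10)
        assert np.all(np.abs(fit.snp_effects - exact) < 3 * mcse + 1e-12)

    def test_null_trait_low_inclusion(self):
        rng = np.random.default_rng(18)
        Z = random_standardized(rng, 50, 30)
        max_incl = []
        for seed in range(4):
            y = rng.standard_normal(50)
            m = McmcSettings(n_iter=1200, burn_in=300, thin=3, reduce_to=None, seed=seed)
            fit = fit_bayesb(Z, y, m)
            max_incl.append(fit.diagnostics["inclusion_prob"].max())
        assert max(max_incl) < 0.8

    def test_marker_reduction_even_spacing(self):
        rng = np.random.default_rng(19)
        Z = random_standardized(rng, 30, 50)
        y = rng.standard_normal(30)
        m = McmcSettings(n_iter=200, burn_in=50, thin=2, reduce_to=10, seed=1)
        fit = fit_bayesb(Z, y, m)
        kept = fit.diagnostics["kept_snp_indices"]
        assert kept.size == 10
        assert kept[0] == 0 and kept[-1] == 49
        # effects on excluded markers are zero
        excluded = np.setdiff1d(np.arange(50), kept)
        assert np.all(fit.snp_effects[excluded] == 0.0)


class TestSharedContracts:
    @pytest.mark.parametrize("model", ["rrblup", "lasso", "elastic_net", "rkhs", "bayesb"])
    def test_intercept_absorbs_constant_shift(self, model):
        """Adding a constant to y shifts predictions by that constant only."""
        rng = np.random.default_rng(20)
        from .conftest import small_sim_config
        from wgpkit.simulate import simulate_genotypes

        cfg = small_sim_config(n_lines=40, n_snps_per_chrom=[12] * 10, seed=23)
        panel = simulate_genotypes(cfg)
        panel, _ = apply_snp_qc(panel)
        y = rng.standard_normal(40)
        shift = 11.3

        def fits(yv, seed=5):
            if model == "rkhs":
                return fit_rkhs(panel, yv, theta_grid=[1.0, 10.0])
            Z = impute_and_standardize(panel)
            if model == "rrblup":
                return fit_rrblup(Z, yv)
            if model == "lasso":
                return fit_lasso(Z, yv, seed=seed)
            if model == "elastic_net":
                return fit_elastic_net(Z, yv, alpha_grid=[0.5, 1.0], seed=seed)
            return fit_bayesb(Z, yv, McmcSettings(n_iter=300, burn_in=100, thin=2,
                                                  reduce_to=None, seed=seed))
        f0 = fits(y)
        f1 = fits(y + shift)
        p0 = predict(f0, panel)
        p1 = predict(f1, panel)
        tol = 1e-8 if model != "bayesb" else 1e-6
        np.testing.assert_allclose(p1 - p0, shift, atol=tol)

    def test_snp_set_mismatch_raises(self):
        rng = np.random.default_rng(21)
        Z = random_standardized(rng, 30, 8)
        y = rng.standard_normal(30)
        fit = fit_rrblup(Z, y)
        from .conftest import toy_panel

        other = toy_panel(rng.choice([0.0, 2.0], size=(5, 3)))
        with pytest.raises(ValueError, match="miss"):
            predict(fit, other)
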