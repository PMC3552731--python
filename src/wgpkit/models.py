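"""Five whole-genome prediction models behind one fit/predict contract.

* RR-BLUP — homogeneous L2 shrinkage; fitted in the kernel-dual space of
  genotypes via the inner-product relationship matrix G = ZZ'/p, with SNP
  effects recovered from the genotype BLUPs.
* LASSO — L1 penalty, glmnet objective convention
  (1/(2n))·RSS + lam·||u||_1, path by cyclic coordinate descent
  (scikit-learn backend), lam chosen by inner k-fold CV MSE.
* Elastic net — mixed penalty lam·(a·||u||_1 + (1-a)/2·||u||_2^2) with an
  (a, lam) grid search by inner CV, ties broken toward sparser models.
* RKHS — Gaussian kernel K_ij = exp(-GD_ij / theta^2) on modified Rogers'
  distances, theta chosen on a grid by restricted maximum likelihood.
* BayesB — per-SNP effect variances with a point mass at zero
  (Metropolis-within-Gibbs), uncertain hyperparameters.

All models operate on column-standardized dosages; new genotypes are
standardized with the *training* means and sds, never re-standardized.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.linear_model import ElasticNet, Lasso, enet_path, lasso_path
from sklearn.model_selection import KFold

from .genotypes import (
    GenotypePanel,
    KernelMatrix,
    StandardizedGenotypes,
    modified_rogers_distance,
)
from .reml import eigen_profile_reml

__all__ = [
    "ModelFit",
    "McmcSettings",
    "fit_rrblup",
    "fit_lasso",
    "fit_elastic_net",
    "fit_rkhs",
    "fit_bayesb",
    "predict",
    "kkt_residual",
    "MODEL_NAMES",
]

MODEL_NAMES = ("rrblup", "lasso", "elastic_net", "rkhs", "bayesb")


@dataclass
class ModelFit:
    """A fitted whole-genome predictor able to score new genotypes."""

    model: str
    mu: float
    snp_effects: np.ndarray | None
    genotype_effects: np.ndarray | None
    hyperparams: dict
    training_line_ids: list[str]
    diagnostics: dict = field(default_factory=dict)
    # training context needed to score new genotypes
    col_means: np.ndarray | None = None
    col_sds: np.ndarray | None = None
    snp_ids: np.ndarray | None = None
    # RKHS / kernel-dual extras
    train_dosages: np.ndarray | None = None
    kernel_weights: np.ndarray | None = None
    theta: float | None = None


def _align_dosages(fit: ModelFit, new) -> np.ndarray:
    """Raw dosage rows aligned to the training SNP set, missing -> train mean."""
    if isinstance(new, StandardizedGenotypes):
        # back to the dosage scale of *its own* panel; SNP sets must match
        ids = [str(s) for s in new.snp_map["snp_id"]]
        if fit.snp_ids is not None and ids != [str(s) for s in fit.snp_ids]:
            raise ValueError("standardized input must carry the training SNP set")
        return new.Z * new.col_sds + new.col_means
    if isinstance(new, GenotypePanel):
        if fit.snp_ids is not None:
            new_ids = [str(s) for s in new.snp_map["snp_id"]]
            train_ids = [str(s) for s in fit.snp_ids]
            if new_ids == train_ids:
                X = new.dosages
            else:
                pos = {s: i for i, s in enumerate(new_ids)}
                missing = [s for s in train_ids if s not in pos]
                if missing:
                    raise ValueError(f"new genotypes miss {len(missing)} training SNPs: "
                                     f"{missing[:5]} ...")
                X = new.dosages[:, [pos[s] for s in train_ids]]
        else:
            X = new.dosages
    else:
        X = np.atleast_2d(np.asarray(new, dtype=float))
    X = X.astype(float).copy()
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(fit.col_means, X.shape)[nan]
    return X


def _standardize_like_training(fit: ModelFit, new) -> np.ndarray:
    """Map a panel / dosage matrix / Z to training-standardized dosages."""
    return (_align_dosages(fit, new) - fit.col_means) / fit.col_sds


# ---------------------------------------------------------------------------
# RR-BLUP (kernel-dual ridge with REML shrinkage)
# ---------------------------------------------------------------------------

def fit_rrblup(
    Z: StandardizedGenotypes,
    y: np.ndarray,
    lambda_rr: float | None = None,
) -> ModelFit:
    """Ridge-regression BLUP via the inner-product kernel G = ZZ'/p.

    The shrinkage parameter lam_RR = s2_e/s2_u is estimated by REML on the
    equivalent genotype-effect model (u treated as random with
    u ~ N(0, I s2_u)), unless ``lambda_rr`` fixes it. SNP effects are then
    recovered from the genotype BLUPs through the dual identity
    u_hat = s2_u Z' V^-1 (y - mu), the numerically stable form of
    u_hat = Z'G^-1 g_hat / p, so that Z u_hat reproduces g_hat exactly.
    """
    y = np.asarray(y, dtype=float)
    if np.var(y) == 0:
        raise ValueError("trait has zero variance")
    n, p = Z.n_lines, Z.n_snps
    G = Z.Z @ Z.Z.T / p
    d, U = np.linalg.eigh(G)
    X = np.ones((n, 1))
    if lambda_rr is None:
        fit = eigen_profile_reml(y, X, (np.maximum(d, 0.0), U))
    else:
        # fixed ratio: gamma = s2_g/s2_e = p / lambda_rr, scale from GLS
        gamma = p / lambda_rr
        w = gamma * np.maximum(d, 0.0) + 1.0
        yt, Xt = U.T @ y, U.T @ X
        Xw = Xt / w[:, None]
        beta = np.linalg.solve(Xt.T @ Xw, Xw.T @ yt)
        r = yt - Xt @ beta
        s2e = float(r @ (r / w)) / (n - X.shape[1])
        from .reml import SingleKernelFit

        fit = SingleKernelFit(gamma * s2e, s2e, beta, np.nan, np.maximum(d, 0.0), U)
    mu = float(fit.beta[0])
    g_hat = fit.blup(y, X)
    vr = fit.vinv_residual(y, X)
    sigma2_u = fit.sigma2_g / p
    u_hat = sigma2_u * (Z.Z.T @ vr)
    lam = np.inf if sigma2_u == 0 else fit.sigma2_e / sigma2_u
    return ModelFit(
        model="rrblup",
        mu=mu,
        snp_effects=u_hat,
        genotype_effects=g_hat,
        hyperparams={
            "sigma2_u": sigma2_u,
            "sigma2_g": fit.sigma2_g,
            "sigma2_e": fit.sigma2_e,
            "lambda_rr": lam,
        },
        training_line_ids=list(Z.line_ids),
        diagnostics={"reml_loglik": fit.loglik},
        col_means=Z.col_means,
        col_sds=Z.col_sds,
        snp_ids=Z.snp_map["snp_id"].to_numpy(),
        train_dosages=None,
        kernel_weights=fit.sigma2_g * vr,  # for the kernel-dual prediction path
    )


def predict_rrblup_dual(fit: ModelFit, Z_train: StandardizedGenotypes, new) -> np.ndarray:
    """Kernel-path prediction mu + G_new,train V^-1 s2_g (y - mu).

    Independent of the SNP-effect path; the two agree to numerical
    precision because G_new,train u-weights factor through the same dual.
    """
    Z_new = _standardize_like_training(fit, new)
    G_cross = Z_new @ Z_train.Z.T / Z_train.n_snps
    return fit.mu + G_cross @ fit.kernel_weights


# ---------------------------------------------------------------------------
# LASSO and elastic net (glmnet objective convention)
# ---------------------------------------------------------------------------

def kkt_residual(Z: np.ndarray, y: np.ndarray, mu: float, u: np.ndarray,
                 lam: float, alpha: float = 1.0) -> float:
    """Max KKT violation of the elastic-net stationarity conditions.

    Objective: (1/(2n))||y - mu - Zu||^2 + lam (alpha ||u||_1
    + (1-alpha)/2 ||u||_2^2). Zero at an exact solution.
    """
    n = y.size
    r = y - mu - Z @ u
    g = -(Z.T @ r) / n + lam * (1.0 - alpha) * u
    viol = np.where(
        u != 0,
        np.abs(g + lam * alpha * np.sign(u)),
        np.maximum(0.0, np.abs(g) - lam * alpha),
    )
    return float(viol.max(initial=0.0))


def _lambda_grid(Z: np.ndarray, y_c: np.ndarray, alpha: float,
                 n_lambda: int, eps: float | None = None) -> np.ndarray:
    n, p = Z.shape
    if eps is None:
        eps = 0.01 if p > n else 1e-3  # glmnet's path-depth convention
    lam_max = float(np.abs(Z.T @ y_c).max()) / (n * max(alpha, 0.001))
    return np.geomspace(lam_max, lam_max * eps, n_lambda)


def _inner_cv_mse(Z, y, alphas_l1, lambdas_by_alpha, n_folds, seed, tol, max_iter):
    """Mean inner-CV MSE for every (alpha, lambda) on a shared fold split."""
    kf = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
    mse = {a: np.zeros(len(lambdas_by_alpha[a])) for a in alphas_l1}
    for tr, va in kf.split(Z):
        Ztr, Zva = Z[tr], Z[va]
        ytr, yva = y[tr], y[va]
        mu = float(ytr.mean())
        for a in alphas_l1:
            lams = lambdas_by_alpha[a]
            if a == 1.0:
                _, coefs, _ = lasso_path(Ztr, ytr - mu, alphas=lams,
                                         max_iter=max_iter, tol=tol)
            else:
                _, coefs, _ = enet_path(Ztr, ytr - mu, l1_ratio=a, alphas=lams,
                                        max_iter=max_iter, tol=tol)
            pred = mu + Zva @ coefs
            mse[a] += np.mean((pred - yva[:, None]) ** 2, axis=0)
    for a in alphas_l1:
        mse[a] /= n_folds
    return mse


def fit_lasso(
    Z: StandardizedGenotypes,
    y: np.ndarray,
    lambda_grid: Sequence[float] | None = None,
    fixed_lambda: float | None = None,
    inner_folds: int = 5,
    n_lambda: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> ModelFit:
    """L1-penalized SNP regression with lam chosen by inner CV MSE.

    The coordinate-descent path follows the glmnet convention
    (1/(2n))·RSS + lam·||u||_1; ties in the CV curve break toward the
    larger (sparser) lam. A ``fixed_lambda`` skips selection.
    """
    return _fit_penalized(Z, y, alphas=(1.0,), lambda_grid=lambda_grid,
                          fixed=(1.0, fixed_lambda) if fixed_lambda is not None else None,
                          inner_folds=inner_folds, n_lambda=n_lambda, seed=seed,
                          tol=tol, max_iter=max_iter, model_name="lasso")


def fit_elastic_net(
    Z: StandardizedGenotypes,
    y: np.ndarray,
    alpha_grid: Sequence[float] | None = None,
    lambda_grid: Sequence[float] | None = None,
    fixed: tuple[float, float] | None = None,
    inner_folds: int = 5,
    n_lambda: int = 50,
    seed: int = 0,
    tol: float = 1e-8,
    max_iter: int = 100_000,
) -> ModelFit:
    """Elastic net with (alpha, lambda) chosen by inner CV MSE on a grid.

    alpha in [0, 1] mixes the ridge (alpha=0) and LASSO (alpha=1)
    penalties; the default grid is 0, 0.1, ..., 1.0. Ties break toward
    larger lambda, then larger alpha (sparser models).
    """
    if alpha_grid is None:
        alpha_grid = np.round(np.arange(0.0, 1.01, 0.1), 2)
    return _fit_penalized(Z, y, alphas=tuple(alpha_grid), lambda_grid=lambda_grid,
                          fixed=fixed, inner_folds=inner_folds, n_lambda=n_lambda,
                          seed=seed, tol=tol, max_iter=max_iter, model_name="elastic_net")


def _solve_enet(Zm, y_c, lam, alpha, tol, max_iter):
    if alpha == 1.0:
        est = Lasso(alpha=lam, fit_intercept=False, tol=tol, max_iter=max_iter)
    else:
        est = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                         tol=tol, max_iter=max_iter)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Zm, y_c)
    return est.coef_.copy()


def _fit_penalized(Z, y, alphas, lambda_grid, fixed, inner_folds, n_lambda,
                   seed, tol, max_iter, model_name):
    y = np.asarray(y, dtype=float)
    if y.size < 10:
        raise ValueError("need at least 10 training lines")
    Zm = Z.Z
    mu = float(y.mean())  # exact intercept: columns of Z are centered
    y_c = y - mu
    if fixed is not None:
        alpha_sel, lam_sel = float(fixed[0]), float(fixed[1])
        cv_mse = None
    else:
        lambdas_by_alpha = {}
        for a in alphas:
            if lambda_grid is not None:
                lambdas_by_alpha[a] = np.sort(np.asarray(lambda_grid, dtype=float))[::-1]
            else:
                lambdas_by_alpha[a] = _lambda_grid(Zm, y_c, a, n_lambda)
        mse = _inner_cv_mse(Zm, y, alphas, lambdas_by_alpha, inner_folds, seed,
                            max(tol, 1e-4), max_iter)

        def select():
            best = None
            tie_eps = 1e-15
            for a in sorted(alphas):  # ascending; ties replace -> larger alpha
                lams = lambdas_by_alpha[a]
                errs = mse[a]
                j = int(np.argmin(errs))  # lams descend: ties pick the largest
                if best is None or errs[j] <= best[0] + tie_eps:
                    best = (float(errs[j]), float(a), float(lams[j]))
            return best

        cv_mse, alpha_sel, lam_sel = select()
        # boundary re-expansion: a minimum on the smallest grid lambda means
        # the CV optimum was clipped by the path depth; extend a decade down
        # (at most twice) and reselect
        extensions = 0
        while (lambda_grid is None and extensions < 2
               and lam_sel <= lambdas_by_alpha[alpha_sel].min() * 1.0001):
            lo = lambdas_by_alpha[alpha_sel].min()
            ext = np.geomspace(lo, lo / 10.0, 11)[1:]
            ext_mse = _inner_cv_mse(Zm, y, (alpha_sel,), {alpha_sel: ext},
                                    inner_folds, seed, max(tol, 1e-4), max_iter)
            lambdas_by_alpha[alpha_sel] = np.r_[lambdas_by_alpha[alpha_sel], ext]
            mse[alpha_sel] = np.r_[mse[alpha_sel], ext_mse[alpha_sel]]
            extensions += 1
            cv_mse, alpha_sel, lam_sel = select()
    u = _solve_enet(Zm, y_c, lam_sel, alpha_sel, tol, max_iter)
    kkt = kkt_residual(Zm, y, mu, u, lam_sel, alpha_sel)
    if kkt > 1e-4:
        raise RuntimeError(
            f"{model_name} coordinate descent did not converge (KKT residual {kkt:.2e})"
        )
    return ModelFit(
        model=model_name,
        mu=mu,
        snp_effects=u,
        genotype_effects=None,
        hyperparams={"lambda": lam_sel, "alpha": alpha_sel,
                     "n_nonzero": int(np.count_nonzero(u)), "inner_cv_mse": cv_mse},
        training_line_ids=list(Z.line_ids),
        diagnostics={"kkt_residual": kkt},
        col_means=Z.col_means,
        col_sds=Z.col_sds,
        snp_ids=Z.snp_map["snp_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# RKHS regression with a Gaussian kernel on modified Rogers' distances
# ---------------------------------------------------------------------------

def default_theta_grid(n_points: int = 30) -> np.ndarray:
    return np.geomspace(0.1, 100.0, n_points)


def fit_rkhs(
    panel: GenotypePanel,
    y: np.ndarray,
    theta_grid: Sequence[float] | None = None,
) -> ModelFit:
    """Gaussian-kernel RKHS regression, bandwidth chosen by REML profile.

    For each theta on the grid, K_ij = exp(-GD_ij / theta^2) is built from
    the modified Rogers' distance matrix, repaired to (numerical) positive
    definiteness if needed, and the single-kernel REML likelihood is
    profiled; the theta with the highest restricted likelihood wins.
    """
    from .partition import nearest_pd  # local import to avoid a cycle

    y = np.asarray(y, dtype=float)
    grid = default_theta_grid() if theta_grid is None else np.asarray(theta_grid, float)
    X = panel.dosages.copy()
    mu_cols = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(mu_cols, X.shape)[nan]
    D = modified_rogers_distance(X)
    ones = np.ones((len(y), 1))
    best = None
    n_repaired = 0
    for theta in grid:
        K = np.exp(-D / theta**2)
        if np.linalg.eigvalsh(K)[0] < 1e-8:
            K = nearest_pd(K)
            n_repaired += 1
        try:
            fit = eigen_profile_reml(y, ones, K)
        except np.linalg.LinAlgError:
            continue
        if best is None or fit.loglik > best[0]:
            best = (fit.loglik, float(theta), fit)
    if best is None:
        raise RuntimeError("REML failed for every theta on the grid")
    _, theta_sel, fit = best
    g_hat = fit.blup(y, ones)
    return ModelFit(
        model="rkhs",
        mu=float(fit.beta[0]),
        snp_effects=None,
        genotype_effects=g_hat,
        hyperparams={"theta": theta_sel, "sigma2_g": fit.sigma2_g,
                     "sigma2_e": fit.sigma2_e},
        training_line_ids=list(panel.line_ids),
        diagnostics={"reml_loglik": fit.loglik, "n_pd_repairs": n_repaired},
        col_means=mu_cols,
        col_sds=np.ones_like(mu_cols),  # distances use raw dosages
        snp_ids=panel.snp_map["snp_id"].to_numpy(),
        train_dosages=X,
        kernel_weights=fit.sigma2_g * fit.vinv_residual(y, ones),
        theta=theta_sel,
    )


# ---------------------------------------------------------------------------
# BayesB (Metropolis-within-Gibbs)
# ---------------------------------------------------------------------------

@dataclass
class McmcSettings:
    """Run protocol and prior switches for the BayesB sampler.

    The default protocol is 50,000 iterations, 5,000 burn-in, thinning 10.
    ``reduce_to`` keeps that many markers, evenly spaced by map position.
    The ``fix_*``/``common_effect_variance`` switches collapse the model to
    a conjugate Bayesian ridge for validation against its closed form.
    """

    n_iter: int = 50_000
    burn_in: int = 5_000
    thin: int = 10
    seed: int = 0
    reduce_to: int | None = 5_000
    # prior hyperparameters (point mass prob ~ Beta, dof/scale ~ Gamma)
    pi_beta: tuple[float, float] = (7.0, 3.0)
    nu_u_gamma: tuple[float, float] = (5.0, 2.0)   # shape k, scale theta
    s2_u_gamma: tuple[float, float] = (0.1, 10.0)
    nu_e: float = 4.001
    # validation switches
    fix_pi: float | None = None
    common_effect_variance: float | None = None
    fix_sigma2_e: float | None = None
    fix_mu: float | None = None
    adapt: bool = True


def _gammaln(x: float) -> float:
    from scipy.special import gammaln

    return float(gammaln(x))


def _sample_invchi2(rng: np.random.Generator, nu: float, s2: float, size=None):
    return nu * s2 / rng.chisquare(nu, size=size)


def fit_bayesb(
    Z: StandardizedGenotypes,
    y: np.ndarray,
    mcmc: McmcSettings | None = None,
) -> ModelFit:
    """BayesB: t-distributed SNP effects with a point mass at zero.

    Per sweep, every SNP gets a joint update of its inclusion indicator
    (effect integrated out), its effect (conjugate normal draw when
    included) and its effect variance (scaled-inverse-chi-square full
    conditional when included, fresh prior draw when excluded, so the
    hyperparameter update conditions on included variances only). The
    residual variance follows its scaled-inverse-chi-square full
    conditional; the point-mass probability its Beta full conditional; the
    effect-variance dof and scale move by random-walk Metropolis on the
    log scale with step sizes adapted during burn-in toward ~30%
    acceptance.
    """
    m = mcmc or McmcSettings()
    rng = np.random.default_rng(m.seed)
    y = np.asarray(y, dtype=float)
    n, p_full = Z.n_lines, Z.n_snps

    if m.reduce_to is not None and p_full > m.reduce_to:
        keep = np.unique(np.round(np.linspace(0, p_full - 1, m.reduce_to)).astype(int))
    else:
        keep = np.arange(p_full)
    Zm = np.ascontiguousarray(Z.Z[:, keep])
    p = keep.size
    ztz = np.einsum("ij,ij->j", Zm, Zm)

    # residual-variance prior scale from the REML fit of the ridge model
    if m.fix_sigma2_e is not None:
        s2e_hat = m.fix_sigma2_e
    else:
        G = Zm @ Zm.T / p
        reml = eigen_profile_reml(y, np.ones((n, 1)), G)
        s2e_hat = max(reml.sigma2_e, 1e-8 * float(np.var(y)))
    nu_e = m.nu_e
    S2_e = s2e_hat * (nu_e - 2.0) / nu_e

    conjugate = m.common_effect_variance is not None
    pi = 0.0 if conjugate else (m.fix_pi if m.fix_pi is not None else
                                m.pi_beta[0] / (m.pi_beta[0] + m.pi_beta[1]))
    nu_u = m.nu_u_gamma[0] * m.nu_u_gamma[1]
    S2_u = m.s2_u_gamma[0] * m.s2_u_gamma[1]
    sigma2_j = (np.full(p, m.common_effect_variance) if conjugate
                else _sample_invchi2(rng, nu_u, S2_u, size=p))
    u = np.zeros(p)
    delta = np.zeros(p, dtype=bool)
    mu = float(y.mean()) if m.fix_mu is None else m.fix_mu
    sigma2_e = s2e_hat
    e = y - mu  # residual y - mu - Z u (u = 0)

    step_nu, step_s2 = 0.3, 0.3
    acc_nu = acc_s2 = try_hyper = 0
    u_sum = np.zeros(p)
    u_sumsq = np.zeros(p)
    incl_sum = np.zeros(p)
    mu_sum = 0.0
    n_kept = 0
    trace = {"pi": [], "nu_u": [], "s2_u": [], "sigma2_e": []}

    for it in range(1, m.n_iter + 1):
        # intercept
        if m.fix_mu is None:
            shift = float(e.mean()) + rng.standard_normal() * np.sqrt(sigma2_e / n)
            mu += shift
            e -= shift

        log_pi = np.log(pi) if pi > 0 else -np.inf
        log_1mpi = np.log1p(-pi) if pi < 1 else -np.inf
        normals = rng.standard_normal(p)
        unifs = rng.random(p)
        for j in range(p):
            zj = Zm[:, j]
            uj = u[j]
            r = float(zj @ e) + ztz[j] * uj  # Z_j' (y - mu - Z_{-j} u)
            s2 = sigma2_j[j]
            v = ztz[j]
            # inclusion indicator with the effect integrated out
            if pi <= 0.0:
                inc = True
            elif pi >= 1.0:
                inc = False
            else:
                l1 = (-0.5 * np.log1p(s2 * v / sigma2_e)
                      + 0.5 * s2 * r * r / (sigma2_e * (sigma2_e + s2 * v)))
                log_odds = log_1mpi + l1 - log_pi
                inc = unifs[j] < 1.0 / (1.0 + np.exp(-log_odds))
            if inc:
                post_var = 1.0 / (v / sigma2_e + 1.0 / s2)
                new_u = post_var * r / sigma2_e + normals[j] * np.sqrt(post_var)
            else:
                new_u = 0.0
            if new_u != uj:
                e -= zj * (new_u - uj)
                u[j] = new_u
            delta[j] = inc

        # per-SNP effect variances
        if not conjugate:
            chi_incl = rng.chisquare(nu_u + 1.0, size=p)
            chi_excl = rng.chisquare(nu_u, size=p)
            incl = delta
            sigma2_j[incl] = (nu_u * S2_u + u[incl] ** 2) / chi_incl[incl]
            sigma2_j[~incl] = nu_u * S2_u / chi_excl[~incl]

        # residual variance
        if m.fix_sigma2_e is None:
            sse = float(e @ e)
            sigma2_e = (nu_e * S2_e + sse) / rng.chisquare(nu_e + n)

        # point-mass probability
        if not conjugate and m.fix_pi is None:
            n1 = int(delta.sum())
            pi = rng.beta(m.pi_beta[0] + (p - n1), m.pi_beta[1] + n1)

        # hyperparameters of the effect-variance prior (MH on log scale)
        if not conjugate:
            incl_s2 = sigma2_j[delta]

            def log_target(nu: float, s2: float) -> float:
                k1, t1 = m.nu_u_gamma
                k2, t2 = m.s2_u_gamma
                lp = ((k1 - 1) * np.log(nu) - nu / t1
                      + (k2 - 1) * np.log(s2) - s2 / t2)
                if incl_s2.size:
                    h = nu / 2.0
                    lp += incl_s2.size * (h * np.log(nu * s2 / 2.0) - _gammaln(h))
                    lp += float(np.sum(-(h + 1.0) * np.log(incl_s2)
                                       - nu * s2 / (2.0 * incl_s2)))
                return lp

            try_hyper += 1
            cur = log_target(nu_u, S2_u)
            prop = nu_u * np.exp(step_nu * rng.standard_normal())
            if np.log(rng.random()) < log_target(prop, S2_u) - cur + np.log(prop / nu_u):
                nu_u = prop
                acc_nu += 1
            cur = log_target(nu_u, S2_u)
            prop = S2_u * np.exp(step_s2 * rng.standard_normal())
            if np.log(rng.random()) < log_target(nu_u, prop) - cur + np.log(prop / S2_u):
                S2_u = prop
                acc_s2 += 1
            if m.adapt and it <= m.burn_in and it % 100 == 0:
                for rate, name in ((acc_nu / try_hyper, "nu"), (acc_s2 / try_hyper, "s2")):
                    fac = np.exp(0.5 * (rate - 0.30))
                    if name == "nu":
                        step_nu = float(np.clip(step_nu * fac, 0.01, 3.0))
                    else:
                        step_s2 = float(np.clip(step_s2 * fac, 0.01, 3.0))

        if it > m.burn_in and (it - m.burn_in) % m.thin == 0:
            n_kept += 1
            u_sum += u
            u_sumsq += u * u
            incl_sum += delta
            mu_sum += mu
            trace["pi"].append(pi)
            trace["nu_u"].append(nu_u)
            trace["s2_u"].append(S2_u)
            trace["sigma2_e"].append(sigma2_e)

    if n_kept == 0:
        raise ValueError("MCMC protocol keeps no samples (check n_iter/burn_in/thin)")
    u_mean_reduced = u_sum / n_kept
    u_mean = np.zeros(p_full)
    u_mean[keep] = u_mean_reduced
    incl_prob = incl_sum / n_kept
    acc_rate_nu = acc_nu / max(try_hyper, 1)
    acc_rate_s2 = acc_s2 / max(try_hyper, 1)
    warnings_list = []
    if not conjugate:
        for nm, rate in (("nu_u", acc_rate_nu), ("s2_u", acc_rate_s2)):
            if not 0.05 <= rate <= 0.95:
                warnings_list.append(f"Metropolis acceptance for {nm} = {rate:.2f} "
                                     "outside [0.05, 0.95]")
    tr = {k: np.asarray(v) for k, v in trace.items()}
    return ModelFit(
        model="bayesb",
        mu=float(mu_sum / n_kept),
        snp_effects=u_mean,
        genotype_effects=None,
        hyperparams={
            "pi_u_mean": float(tr["pi"].mean()) if tr["pi"].size else pi,
            "nu_u_mean": float(tr["nu_u"].mean()) if tr["nu_u"].size else nu_u,
            "s2_u_mean": float(tr["s2_u"].mean()) if tr["s2_u"].size else S2_u,
            "sigma2_e_mean": float(tr["sigma2_e"].mean()) if tr["sigma2_e"].size else sigma2_e,
            "S2_e_prior_scale": S2_e,
        },
        training_line_ids=list(Z.line_ids),
        diagnostics={
            "n_samples": n_kept,
            "acceptance_nu_u": acc_rate_nu,
            "acceptance_s2_u": acc_rate_s2,
            "inclusion_prob": incl_prob,
            "kept_snp_indices": keep,
            "posterior_sd": np.sqrt(np.maximum(u_sumsq / n_kept - u_mean_reduced**2, 0.0)),
            "warnings": warnings_list,
            "trace": tr,
        },
        col_means=Z.col_means,
        col_sds=Z.col_sds,
        snp_ids=Z.snp_map["snp_id"].to_numpy(),
    )


# ---------------------------------------------------------------------------
# Prediction
# ---------------------------------------------------------------------------

def predict(fit: ModelFit, new) -> np.ndarray:
    """Score new genotypes with a fitted model.

    Effect-based models compute mu + Z_new u_hat with Z_new standardized by
    the training statistics; the RKHS model computes the cross-kernel row
    k(new, training) against the stored kernel weights. Passing the
    training panel back reproduces the fitted values.
    """
    if fit.model == "rkhs":
        X_new = _align_dosages(fit, new)
        p = fit.train_dosages.shape[1]
        if X_new.shape[1] != p:
            raise ValueError("SNP set mismatch with training panel")
        d2 = (
            np.sum(X_new**2, axis=1)[:, None]
            + np.sum(fit.train_dosages**2, axis=1)[None, :]
            - 2.0 * X_new @ fit.train_dosages.T
        )
        GD = np.sqrt(np.maximum(d2, 0.0)) / (2.0 * np.sqrt(p))
        K_cross = np.exp(-GD / fit.theta**2)
        return fit.mu + K_cross @ fit.kernel_weights
    Z_new = _standardize_like_training(fit, new)
    return fit.mu + Z_new @ fit.snp_effects
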