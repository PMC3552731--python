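"""Restricted maximum likelihood machinery for kernel mixed models.

Two fitters are provided:

* :func:`eigen_profile_reml` — a single-kernel fitter that diagonalizes the
  kernel once and profiles the restricted likelihood over the variance
  ratio, used by the ridge (kernel-dual) and RKHS predictors.
* :func:`fit_multi_kernel_reml` — a many-kernel fitter (EM warm-up with
  average-information acceleration and an active set for the non-negativity
  constraints), used for partitioning genetic variance across chromosomes.

The model throughout is y = X b + sum_k g_k + e with g_k ~ N(0, K_k s2_k)
and e ~ N(0, I s2_e); V = sum_k s2_k K_k + s2_e I.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "reml_loglik",
    "eigen_profile_reml",
    "fit_multi_kernel_reml",
    "MultiKernelFit",
    "SingleKernelFit",
]

_LOG2PI = float(np.log(2.0 * np.pi))


def reml_loglik(y: np.ndarray, X: np.ndarray, V: np.ndarray) -> float:
    """Restricted log-likelihood of y ~ N(Xb, V), b profiled out."""
    n, q = X.shape
    c, low = cho_factor(V, lower=True)
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    Vi_X = cho_solve((c, low), X)
    Vi_y = cho_solve((c, low), y)
    XtViX = X.T @ Vi_X
    s, logdet_XtViX = np.linalg.slogdet(XtViX)
    if s <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    beta = np.linalg.solve(XtViX, X.T @ Vi_y)
    Py = Vi_y - Vi_X @ beta
    quad = float(y @ Py)
    return -0.5 * (logdet_V + logdet_XtViX + quad + (n - q) * _LOG2PI)


@dataclass
class SingleKernelFit:
    sigma2_g: float
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    # eigen transform retained for cheap BLUP computation
    eigvals: np.ndarray
    eigvecs: np.ndarray

    @property
    def lambda_ratio(self) -> float:
        """Shrinkage ratio s2_e / s2_g (infinite when s2_g = 0)."""
        return np.inf if self.sigma2_g == 0 else self.sigma2_e / self.sigma2_g

    def blup(self, y: np.ndarray, X: np.ndarray) -> np.ndarray:
        """BLUP of the genotypic effects, g_hat = s2_g K V^-1 (y - Xb)."""
        U, d = self.eigvecs, self.eigvals
        w = self.sigma2_g * d + self.sigma2_e
        r = U.T @ (y - X @ self.beta)
        return U @ (self.sigma2_g * d * r / w)

    def vinv_residual(self, y: np.ndarray, X: np.ndarray) -> np.ndarray:
        """V^-1 (y - Xb): the weight vector for cross-kernel prediction."""
        U, d = self.eigvecs, self.eigvals
        w = self.sigma2_g * d + self.sigma2_e
        r = U.T @ (y - X @ self.beta)
        return U @ (r / w)


def eigen_profile_reml(
    y: np.ndarray,
    X: np.ndarray,
    K: np.ndarray | tuple[np.ndarray, np.ndarray],
    log_gamma_bounds: tuple[float, float] = (-15.0, 15.0),
) -> SingleKernelFit:
    """REML for a single-kernel model by profiling over gamma = s2_g/s2_e.

    ``K`` may be the kernel matrix or a precomputed ``(eigvals, eigvecs)``
    pair. The scale s2_e is profiled out analytically, leaving a 1-D
    maximization over log gamma solved by bounded scalar search (with the
    gamma -> 0 boundary checked explicitly).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n, q = X.shape
    if isinstance(K, tuple):
        d, U = K
    else:
        d, U = np.linalg.eigh(np.asarray(K, dtype=float))
    d = np.maximum(d, 0.0)
    yt = U.T @ y
    Xt = U.T @ X

    def profiled(log_gamma: float) -> tuple[float, float, np.ndarray]:
        gamma = np.exp(log_gamma)
        w = gamma * d + 1.0  # V = s2_e * diag(w) in the eigenbasis
        Xw = Xt / w[:, None]
        XtWX = Xt.T @ Xw
        beta = np.linalg.solve(XtWX, Xw.T @ yt)
        r = yt - Xt @ beta
        rss = float(r @ (r / w))
        s2e = rss / (n - q)
        s, logdet_XtWX = np.linalg.slogdet(XtWX)
        ll = -0.5 * (
            (n - q) * np.log(s2e)
            + float(np.sum(np.log(w)))
            + logdet_XtWX
            + (n - q)
            + (n - q) * _LOG2PI
        )
        return ll, s2e, beta

    res = optimize.minimize_scalar(
        lambda lg: -profiled(lg)[0], bounds=log_gamma_bounds, method="bounded",
        options={"xatol": 1e-8},
    )
    ll_opt, s2e_opt, beta_opt = profiled(float(res.x))
    gamma_opt = float(np.exp(res.x))
    # explicit gamma -> 0 boundary (no genetic variance)
    w0 = np.ones(n)
    X0 = Xt
    XtWX0 = X0.T @ X0
    beta0 = np.linalg.solve(XtWX0, X0.T @ yt)
    r0 = yt - X0 @ beta0
    s2e0 = float(r0 @ r0) / (n - q)
    ll0 = -0.5 * (
        (n - q) * np.log(s2e0) + float(np.linalg.slogdet(XtWX0)[1]) + (n - q) + (n - q) * _LOG2PI
    )
    if ll0 > ll_opt:
        return SingleKernelFit(0.0, s2e0, beta0, ll0, d, U)
    return SingleKernelFit(gamma_opt * s2e_opt, s2e_opt, beta_opt, ll_opt, d, U)


@dataclass
class MultiKernelFit:
    sigma2: np.ndarray  # one component per kernel
    sigma2_e: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int


def _reml_quantities(y, X, kernels, theta):
    """V^-1-based quantities shared by the score/AI computations."""
    n = y.size
    V = theta[-1] * np.eye(n)
    for s2, K in zip(theta[:-1], kernels):
        if s2 > 0:
            V += s2 * K
    c, low = cho_factor(V, lower=True)
    Vi = cho_solve((c, low), np.eye(n))
    logdet_V = 2.0 * float(np.sum(np.log(np.diag(c))))
    XtViX = X.T @ Vi @ X
    XtViX_inv = np.linalg.inv(XtViX)
    P = Vi - Vi @ X @ XtViX_inv @ X.T @ Vi
    Py = P @ y
    beta = XtViX_inv @ X.T @ Vi @ y
    q = X.shape[1]
    sign, logdet_XtViX = np.linalg.slogdet(XtViX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    ll = -0.5 * (logdet_V + logdet_XtViX + float(y @ Py) + (n - q) * _LOG2PI)
    return P, Py, beta, ll


def fit_multi_kernel_reml(
    y: np.ndarray,
    X: np.ndarray,
    kernels: list[np.ndarray],
    tol: float = 1e-6,
    max_iter: int = 200,
    n_em_warmup: int = 5,
) -> MultiKernelFit:
    """REML for V = sum_k s2_k K_k + s2_e I with s2_k >= 0.

    EM warm-up iterations stabilize the start, after which average-
    information (AI) steps accelerate convergence; step-halving guards the
    likelihood and an active set pins components whose updates go negative
    at zero (they re-enter when their score turns positive). Convergence is
    declared when the restricted log-likelihood changes by less than
    ``tol``; hitting ``max_iter`` flags ``converged=False`` rather than
    raising.
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n = y.size
    m = len(kernels)
    vy = float(np.var(y))
    if vy <= 0:
        raise ValueError("trait has zero variance")
    theta = np.full(m + 1, 0.5 * vy / m)
    theta[-1] = 0.5 * vy
    pinned = np.zeros(m + 1, dtype=bool)
    floor = 1e-10 * vy

    P, Py, beta, ll = _reml_quantities(y, X, kernels, theta)
    n_iter = 0
    converged = False
    for n_iter in range(1, max_iter + 1):
        mats = [K @ Py for K in kernels] + [Py]
        trPK = np.empty(m + 1)
        for k, K in enumerate(kernels):
            trPK[k] = float(np.sum(P * K))  # tr(P K) for symmetric K
        trPK[-1] = float(np.trace(P))
        quad = np.array([float(Py @ u) for u in mats])
        score = -0.5 * (trPK - quad)

        # release pinned components whose score pushes them positive
        pinned &= ~(score > 0)
        pinned[-1] = False  # residual never pinned

        free = ~pinned
        if n_iter <= n_em_warmup:
            new = theta + theta**2 * (quad - trPK) / n
        else:
            PU = [P @ u for u in mats]
            idx = np.where(free)[0]
            AI = 0.5 * np.array(
                [[float(mats[i] @ PU[j]) for j in idx] for i in idx]
            )
            delta = np.zeros(m + 1)
            try:
                delta[idx] = np.linalg.solve(AI + 1e-12 * np.eye(len(idx)) * np.trace(AI), score[idx])
            except np.linalg.LinAlgError:
                delta = theta**2 * (quad - trPK) / n
            new = theta + delta
        new[pinned] = 0.0

        # pin components driven negative
        neg = new < floor
        neg[-1] = False
        new[neg] = 0.0
        pinned |= neg
        new[-1] = max(new[-1], floor)

        # step-halving toward the previous point if the likelihood drops
        step = 1.0
        for _ in range(20):
            cand = theta + step * (new - theta)
            cand[cand < 0] = 0.0
            cand[-1] = max(cand[-1], floor)
            try:
                P_c, Py_c, beta_c, ll_c = _reml_quantities(y, X, kernels, cand)
            except np.linalg.LinAlgError:
                step /= 2.0
                continue
            if ll_c >= ll - 1e-10:
                break
            step /= 2.0
        else:
            # no improving step exists: numerically stationary
            converged = True
            break
        d_ll = ll_c - ll
        theta, P, Py, beta, ll = cand, P_c, Py_c, beta_c, ll_c
        if abs(d_ll) < tol and n_iter > n_em_warmup:
            converged = True
            break

    return MultiKernelFit(
        sigma2=theta[:-1].copy(),
        sigma2_e=float(theta[-1]),
        beta=beta,
        loglik=float(ll),
        converged=converged,
        n_iter=n_iter,
    )
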