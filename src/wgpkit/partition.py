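"""Genome partitioning of genetic variance and the supporting GWA scan.

The partition model fits, by restricted maximum likelihood, one random
genotypic effect per chromosome (covariance G_c = Z_c Z_c'/p_c) plus a
residual, with the first ten principal components of the SNP matrix as
fixed covariates to absorb population structure:

    y = 1 mu + Q b + sum_c g_c + e,   g_c ~ N(0, G_c s2_gc)

The variance attributable to chromosome c is reported as the share
s2_gc / (sum_c s2_gc + s2_e). Chromosome kernels are often numerically
singular at these SNP counts; they are repaired to positive definiteness
with Higham's alternating-projection algorithm before fitting.

A single-marker mixed-model scan (structure + kinship corrected,
null-model variance components reused per SNP) localizes major QTL, and a
chromosome-length regression quantifies the polygenic expectation that
longer chromosomes capture more genetic variance.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .genotypes import KernelMatrix, StandardizedGenotypes, TraitRecord
from .reml import MultiKernelFit, fit_multi_kernel_reml

__all__ = [
    "PartitionModelSpec",
    "PartitionResult",
    "GWAResult",
    "compute_pcs",
    "nearest_pd",
    "fit_partition",
    "chromosome_length_regression",
    "gwa_scan",
]


def compute_pcs(Z: StandardizedGenotypes, k: int) -> np.ndarray:
    """Top-k principal-component scores of the standardized SNP matrix.

    Scores are U*S from the thin SVD of Z, ordered by decreasing singular
    value. k=0 yields an empty (n, 0) matrix (intercept-only correction).
    """
    n = Z.n_lines
    if k >= n:
        raise ValueError(f"k={k} must be smaller than the number of lines ({n})")
    if k == 0:
        return np.empty((n, 0))
    U, s, _ = np.linalg.svd(Z.Z, full_matrices=False)
    return U[:, :k] * s[:k]


def nearest_pd(M: np.ndarray, eig_floor: float = 1e-8, max_iter: int = 100,
               tol: float = 1e-10) -> np.ndarray:
    """Nearest (Frobenius) positive semidefinite matrix, floored to PD.

    Higham's alternating projections between the symmetric matrices and the
    PSD cone; for a plain symmetric input (no unit-diagonal constraint) the
    projection converges immediately to the eigenvalue-clipped matrix, and
    a small eigenvalue floor then makes the result numerically positive
    definite.
    """
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1] or not np.allclose(M, M.T, atol=1e-8):
        raise ValueError("input must be a symmetric square matrix")
    Y = (M + M.T) / 2.0
    for _ in range(max_iter):
        d, V = np.linalg.eigh(Y)
        X = (V * np.maximum(d, 0.0)) @ V.T
        X = (X + X.T) / 2.0
        if np.linalg.norm(X - Y, "fro") <= tol * max(1.0, np.linalg.norm(Y, "fro")):
            Y = X
            break
        Y = X
    d, V = np.linalg.eigh(Y)
    return (V * np.maximum(d, eig_floor)) @ V.T


@dataclass
class PartitionModelSpec:
    """Inputs of the chromosome-partition REML fit."""

    kernels: list[KernelMatrix]
    trait: TraitRecord
    Q: np.ndarray  # n x n_pcs principal-component scores
    reml_tol: float = 1e-6
    max_iter: int = 200
    pd_eig_threshold: float = 1e-8

    def __post_init__(self) -> None:
        n = len(self.trait.values)
        if any(k.values.shape[0] != n for k in self.kernels):
            raise ValueError("kernel dimension does not match trait length")
        if self.Q.shape[0] != n:
            raise ValueError("PC matrix dimension does not match trait length")


@dataclass
class PartitionResult:
    sigma2_gc: np.ndarray
    sigma2_e: float
    shares: np.ndarray
    residual_share: float
    beta: np.ndarray
    loglik: float
    converged: bool
    n_iter: int
    n_pd_repairs: int
    chromosomes: list[int]

    def to_frame(self, chrom_lengths: list[int] | None = None,
                 n_snps: list[int] | None = None) -> pd.DataFrame:
        df = pd.DataFrame({
            "chrom": self.chromosomes,
            "sigma2_gc": self.sigma2_gc,
            "share": self.shares,
        })
        if n_snps is not None:
            df["n_snps"] = n_snps
        if chrom_lengths is not None:
            df["length_bp"] = chrom_lengths
        df["cumulative_share"] = np.cumsum(self.shares)
        return df


def fit_partition(spec: PartitionModelSpec) -> PartitionResult:
    """REML estimation of per-chromosome genetic variances and their shares.

    Kernels with smallest eigenvalue below ``pd_eig_threshold`` are
    repaired with :func:`nearest_pd` before fitting. Non-convergence
    after ``max_iter`` flags the result rather than raising.
    """
    y = spec.trait.values.astype(float)
    n = y.size
    X = np.column_stack([np.ones(n), spec.Q])
    kernels = []
    n_repairs = 0
    for km in spec.kernels:
        V = km.values
        if np.linalg.eigvalsh(V)[0] < spec.pd_eig_threshold:
            V = nearest_pd(V, eig_floor=spec.pd_eig_threshold)
            n_repairs += 1
        kernels.append(V)
    fit: MultiKernelFit = fit_multi_kernel_reml(
        y, X, kernels, tol=spec.reml_tol, max_iter=spec.max_iter
    )
    total = float(fit.sigma2.sum() + fit.sigma2_e)
    shares = fit.sigma2 / total
    return PartitionResult(
        sigma2_gc=fit.sigma2,
        sigma2_e=fit.sigma2_e,
        shares=shares,
        residual_share=fit.sigma2_e / total,
        beta=fit.beta,
        loglik=fit.loglik,
        converged=fit.converged,
        n_iter=fit.n_iter,
        n_pd_repairs=n_repairs,
        chromosomes=[k.chromosome if k.chromosome is not None else i + 1
                     for i, k in enumerate(spec.kernels)],
    )


def chromosome_length_regression(
    result: PartitionResult,
    chrom_lengths: list[int],
    exclude: set[int] | None = None,
) -> tuple[float, float]:
    """Pearson correlation of chromosome length with estimated share.

    Chromosomes carrying declared QTL are excluded first; fewer than three
    remaining points or a degenerate (constant) share vector is an error.
    """
    exclude = exclude or set()
    mask = np.array([c not in exclude for c in result.chromosomes])
    if mask.sum() < 3:
        raise ValueError("need at least 3 chromosomes after exclusion")
    x = np.asarray(chrom_lengths, dtype=float)[mask]
    s = result.shares[mask]
    if np.std(s) == 0 or np.std(x) == 0:
        raise ValueError("degenerate input: shares or lengths are constant")
    r, p = stats.pearsonr(x, s)
    return float(r), float(p)


@dataclass
class GWAResult:
    table: pd.DataFrame  # snp_id, chrom, pos, beta, se, p, explained_gv
    bonferroni_threshold: float
    null_sigma2_g: float
    null_sigma2_e: float

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["p"] < self.bonferroni_threshold]

    def top_snp(self) -> pd.Series:
        return self.table.loc[self.table["p"].idxmin()]


def gwa_scan(
    Z: StandardizedGenotypes,
    trait: TraitRecord,
    K: KernelMatrix,
    Q: np.ndarray,
    alpha: float = 0.01,
) -> GWAResult:
    """Single-marker mixed-model association scan with Q + K correction.

    Variance components are estimated once on the null model
    y = 1 mu + Q b + g + e (g ~ N(0, K s2_g)) and then held fixed for the
    per-SNP Wald tests — the population-parameters-previously-determined
    approximation. The Bonferroni threshold is alpha / p. A SNP's
    "explained genetic variance" is its squared correlation with the trait
    divided by the trait's heritability.
    """
    from .reml import eigen_profile_reml

    if trait.h2 <= 0:
        raise ValueError("explained genetic variance undefined for h2 <= 0")
    y = trait.values.astype(float)
    n, p = Z.n_lines, Z.n_snps
    X0 = np.column_stack([np.ones(n), Q])
    null = eigen_profile_reml(y, X0, K.values)
    # whiten with the null covariance: V = s2_g K + s2_e I
    d, U = null.eigvals, null.eigvecs
    w = null.sigma2_g * d + null.sigma2_e
    sqrt_wi = 1.0 / np.sqrt(w)
    yt = (U.T @ y) * sqrt_wi
    X0t = (U.T @ X0) * sqrt_wi[:, None]
    Zt = (U.T @ Z.Z) * sqrt_wi[:, None]
    # residualize the SNPs and the trait against the null fixed effects
    Q0, _ = np.linalg.qr(X0t)
    y_res = yt - Q0 @ (Q0.T @ yt)
    Z_res = Zt - Q0 @ (Q0.T @ Zt)
    ztz = np.einsum("ij,ij->j", Z_res, Z_res)
    dof = n - X0.shape[1] - 1
    ok = ztz > 1e-12
    beta = np.zeros(p)
    se = np.full(p, np.nan)
    pvals = np.ones(p)
    beta[ok] = (Z_res[:, ok].T @ y_res) / ztz[ok]
    rss = float(y_res @ y_res) - beta[ok] ** 2 * ztz[ok]
    sigma2 = np.maximum(rss / dof, 1e-300)
    se_ok = np.sqrt(sigma2 / ztz[ok])
    tstat = beta[ok] / se_ok
    se[ok] = se_ok
    pvals[ok] = 2.0 * stats.t.sf(np.abs(tstat), dof)

    yc = y - y.mean()
    num = (Z.Z * yc[:, None]).sum(axis=0)
    denom = np.sqrt((Z.Z**2).sum(axis=0) * float(yc @ yc))
    r2 = np.zeros(p)
    nz = denom > 0
    r2[nz] = (num[nz] / denom[nz]) ** 2
    explained_gv = r2 / trait.h2

    table = pd.DataFrame({
        "snp_id": Z.snp_map["snp_id"].to_numpy(),
        "chrom": Z.snp_map["chrom"].to_numpy(),
        "pos": Z.snp_map["pos"].to_numpy(),
        "beta": beta,
        "se": se,
        "p": pvals,
        "explained_gv": explained_gv,
    })
    return GWAResult(
        table=table,
        bonferroni_threshold=alpha / p,
        null_sigma2_g=null.sigma2_g,
        null_sigma2_e=null.sigma2_e,
    )


def write_partition_tsv(result: PartitionResult, path: str | Path,
                        chrom_lengths: list[int] | None = None,
                        n_snps: list[int] | None = None) -> None:
    result.to_frame(chrom_lengths, n_snps).to_csv(path, sep="\t", index=False,
                                                  float_format="%.6g")


def write_gwa_tsv(result: GWAResult, path: str | Path) -> None:
    result.table.to_csv(path, sep="\t", index=False, float_format="%.6g")
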