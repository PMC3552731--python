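"""Genotype containers, SNP quality control, standardization and kernels.

Dosages count copies of the minor allele (0/1/2) for a panel of inbred
lines; missing calls are NaN. Quality control mirrors standard SNP-chip
preprocessing for inbred diversity panels: per-SNP missingness, minor
allele frequency, heterozygote count, and consistency of replicated check
genotypes. Retained SNPs are mean-imputed and standardized column-wise,
from which the genomic relationship matrix G = ZZ'/p (whole-genome or
per-chromosome) and the Gaussian kernel on modified Rogers' distances are
built.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

__all__ = [
    "GenotypePanel",
    "TraitRecord",
    "StandardizedGenotypes",
    "KernelMatrix",
    "QcReport",
    "apply_snp_qc",
    "impute_and_standardize",
    "build_grm",
    "modified_rogers_distance",
    "ld_r2_profile",
    "read_genotype_tsv",
    "read_phenotype_tsv",
    "read_vcf",
    "write_genotype_tsv",
    "write_kernel_tsv",
]


class PanelError(ValueError):
    """Raised for structurally invalid genotype panels."""


@dataclass
class GenotypePanel:
    """n lines x p SNPs minor-allele dosage matrix with a SNP map.

    Parameters
    ----------
    dosages
        Float array of shape (n, p) with values in {0, 1, 2} or NaN.
    line_ids
        Unique identifiers of the n lines.
    snp_map
        DataFrame with columns ``snp_id``, ``chrom`` (1-based integer) and
        ``pos`` (1-based bp), one row per SNP column, positions strictly
        increasing within chromosome.
    check_replicate_groups
        Optional mapping group-name -> list of line_ids that are replicates
        of the same genotype (used by the replicate-consistency QC filter).
    """

    dosages: np.ndarray
    line_ids: list[str]
    snp_map: pd.DataFrame
    check_replicate_groups: dict[str, list[str]] | None = None

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.ndim != 2:
            raise PanelError("dosages must be a 2-D matrix")
        n, p = self.dosages.shape
        if n == 0 or p == 0:
            raise PanelError("panel must contain at least one line and one SNP")
        if len(self.line_ids) != n:
            raise PanelError("line_ids length does not match dosage rows")
        if len(set(self.line_ids)) != n:
            raise PanelError("line_ids must be unique")
        if len(self.snp_map) != p:
            raise PanelError("snp_map length does not match dosage columns")
        vals = self.dosages[~np.isnan(self.dosages)]
        if vals.size and not np.isin(vals, (0.0, 1.0, 2.0)).all():
            raise PanelError("dosage values must be in {0, 1, 2} or missing")
        for _, sub in self.snp_map.groupby("chrom"):
            if not np.all(np.diff(sub["pos"].to_numpy()) > 0):
                raise PanelError("positions must be strictly increasing within chromosome")

    @property
    def n_lines(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, mask: np.ndarray) -> "GenotypePanel":
        return replace(
            self,
            dosages=self.dosages[:, mask],
            snp_map=self.snp_map.loc[mask].reset_index(drop=True),
        )


@dataclass
class TraitRecord:
    """Genotypic means of one trait with its line-mean heritability."""

    trait: str
    line_ids: list[str]
    values: np.ndarray
    h2: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(self.line_ids) != self.values.size:
            raise ValueError("line_ids and values length mismatch")
        if not 0 < self.h2 <= 1:
            raise ValueError("h2 must be in (0, 1]")

    def aligned_to(self, line_ids: Sequence[str]) -> np.ndarray:
        """Trait values reordered to match a panel's line order."""
        idx = {lid: i for i, lid in enumerate(self.line_ids)}
        try:
            order = [idx[lid] for lid in line_ids]
        except KeyError as exc:  # pragma: no cover - defensive
            raise ValueError(f"trait has no value for line {exc}") from exc
        return self.values[order]


@dataclass
class StandardizedGenotypes:
    """Column-standardized allele dosages Z with the statistics used."""

    Z: np.ndarray
    col_means: np.ndarray
    col_sds: np.ndarray
    snp_map: pd.DataFrame
    line_ids: list[str]

    @property
    def n_lines(self) -> int:
        return self.Z.shape[0]

    @property
    def n_snps(self) -> int:
        return self.Z.shape[1]

    def chromosome_columns(self, chromosome: int) -> np.ndarray:
        mask = (self.snp_map["chrom"].to_numpy() == chromosome)
        if not mask.any():
            raise ValueError(f"no SNPs on chromosome {chromosome}")
        return mask

    def standardize_new(self, dosages: np.ndarray) -> np.ndarray:
        """Standardize new dosage rows with the *training* means/sds.

        Missing entries are imputed to the training column mean (i.e. a
        standardized value of zero), never re-estimated from the new data.
        """
        X = np.array(dosages, dtype=float)
        nan = np.isnan(X)
        if nan.any():
            X[nan] = np.broadcast_to(self.col_means, X.shape)[nan]
        return (X - self.col_means) / self.col_sds


@dataclass
class KernelMatrix:
    """Symmetric n x n relationship or kernel matrix with provenance."""

    values: np.ndarray
    kind: str  # inner_product_G | chromosome_Gc | gaussian_K
    line_ids: list[str]
    chromosome: int | None = None
    theta: float | None = None
    n_snps: int | None = None
    psd_repaired: bool = False

    def __post_init__(self) -> None:
        V = np.asarray(self.values, dtype=float)
        if V.ndim != 2 or V.shape[0] != V.shape[1]:
            raise ValueError("kernel must be square")
        if not np.allclose(V, V.T, atol=1e-10):
            raise ValueError("kernel must be symmetric")
        self.values = (V + V.T) / 2.0

    def min_eigenvalue(self) -> float:
        return float(np.linalg.eigvalsh(self.values)[0])


@dataclass
class QcReport:
    """Per-criterion SNP removal counts from :func:`apply_snp_qc`."""

    n_input: int
    n_removed_missing: int
    n_removed_maf: int
    n_removed_het: int
    n_removed_replicate: int
    n_retained: int
    thresholds: dict = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "criterion": [
                    "missing_rate",
                    "minor_allele_frequency",
                    "heterozygote_count",
                    "replicate_consistency",
                    "retained",
                ],
                "n_snps": [
                    self.n_removed_missing,
                    self.n_removed_maf,
                    self.n_removed_het,
                    self.n_removed_replicate,
                    self.n_retained,
                ],
            }
        )


# ---------------------------------------------------------------------------
# Quality control
# ---------------------------------------------------------------------------

def _minor_allele_frequency(dosages: np.ndarray) -> np.ndarray:
    """Per-SNP minor allele frequency, ignoring missing calls."""
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dosages, axis=0) / 2.0
    return np.minimum(freq, 1.0 - freq)


def apply_snp_qc(
    panel: GenotypePanel,
    max_missing: float = 0.10,
    min_maf: float = 0.025,
    max_het: int = 3,
) -> tuple[GenotypePanel, QcReport]:
    """Apply per-SNP quality filters and re-orient dosages to the minor allele.

    A SNP is removed if it has (i) a missing-call fraction strictly greater
    than ``max_missing``, (ii) minor allele frequency not *greater than*
    ``min_maf`` (a SNP at exactly the threshold is removed), (iii) more than
    ``max_het`` heterozygous calls, or (iv) conflicting non-missing calls
    among declared replicates of the same genotype. The filters are
    independent per-SNP predicates, so the retained set does not depend on
    the order in which they are applied; each SNP is counted under the first
    criterion (in the order above) that it violates.

    Retained SNPs are re-coded so that the dosage counts the minor allele in
    the retained panel (ties at MAF 0.5 keep the input orientation).
    """
    X = panel.dosages
    n, p = X.shape

    miss_frac = np.isnan(X).mean(axis=0)
    bad_missing = miss_frac > max_missing

    maf = _minor_allele_frequency(X)
    # monomorphic (maf 0) also fails here
    bad_maf = ~(maf > min_maf)

    n_het = np.nansum(X == 1.0, axis=0)
    bad_het = n_het > max_het

    bad_rep = np.zeros(p, dtype=bool)
    if panel.check_replicate_groups:
        row_of = {lid: i for i, lid in enumerate(panel.line_ids)}
        for members in panel.check_replicate_groups.values():
            rows = [row_of[m] for m in members if m in row_of]
            if len(rows) < 2:
                continue
            sub = X[rows]
            valid = ~np.isnan(sub)
            enough = valid.sum(axis=0) >= 2
            lo = np.where(valid, sub, np.inf).min(axis=0)
            hi = np.where(valid, sub, -np.inf).max(axis=0)
            bad_rep |= enough & (hi > lo)

    removed_missing = bad_missing
    removed_maf = bad_maf & ~bad_missing
    removed_het = bad_het & ~bad_missing & ~bad_maf
    removed_rep = bad_rep & ~bad_missing & ~bad_maf & ~bad_het
    keep = ~(bad_missing | bad_maf | bad_het | bad_rep)

    if not keep.any():
        raise PanelError("all SNPs removed by quality control")

    out = panel.subset_snps(keep)
    # minor-allele orientation: flip SNPs whose coded allele frequency > 0.5
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(out.dosages, axis=0) / 2.0
    flip = freq > 0.5
    if flip.any():
        D = out.dosages.copy()
        D[:, flip] = 2.0 - D[:, flip]
        out = replace(out, dosages=D)

    report = QcReport(
        n_input=p,
        n_removed_missing=int(removed_missing.sum()),
        n_removed_maf=int(removed_maf.sum()),
        n_removed_het=int(removed_het.sum()),
        n_removed_replicate=int(removed_rep.sum()),
        n_retained=int(keep.sum()),
        thresholds={"max_missing": max_missing, "min_maf": min_maf, "max_het": max_het},
    )
    return out, report


# ---------------------------------------------------------------------------
# Imputation, standardization, kernels
# ---------------------------------------------------------------------------

def impute_and_standardize(panel: GenotypePanel) -> StandardizedGenotypes:
    """SNP-mean imputation followed by column centering and unit-sd scaling.

    The standard deviation uses the population denominator (divide by n) so
    that the mean diagonal of G = ZZ'/p is exactly 1 for the training panel.
    """
    X = panel.dosages.copy()
    means = np.nanmean(X, axis=0)
    nan = np.isnan(X)
    if nan.any():
        X[nan] = np.broadcast_to(means, X.shape)[nan]
    means = X.mean(axis=0)
    sds = X.std(axis=0)  # ddof=0
    zero = sds <= 0
    if zero.any():
        bad = panel.snp_map["snp_id"].to_numpy()[zero]
        raise PanelError(f"monomorphic SNP(s) cannot be standardized: {', '.join(map(str, bad[:5]))}")
    Z = (X - means) / sds
    return StandardizedGenotypes(
        Z=Z,
        col_means=means,
        col_sds=sds,
        snp_map=panel.snp_map.reset_index(drop=True),
        line_ids=list(panel.line_ids),
    )


def build_grm(Z: StandardizedGenotypes, chromosome: int | None = None) -> KernelMatrix:
    """Genomic relationship matrix G = ZZ'/p (whole genome or one chromosome)."""
    if chromosome is None:
        M = Z.Z
        kind = "inner_product_G"
    else:
        M = Z.Z[:, Z.chromosome_columns(chromosome)]
        kind = "chromosome_Gc"
    p = M.shape[1]
    G = M @ M.T / p
    return KernelMatrix(
        values=G, kind=kind, line_ids=list(Z.line_ids), chromosome=chromosome, n_snps=p
    )


def modified_rogers_distance(dosages: np.ndarray) -> np.ndarray:
    """Modified Rogers' genetic distance between all pairs of lines.

    GD_ij = sqrt( sum_k (x_ik - x_jk)^2 / (4 p) ) for dosages x in {0,1,2}:
    the Euclidean distance on within-line allele frequencies, scaled so the
    maximal biallelic contrast (0 vs 2 at every locus) maps to exactly 1 and
    a heterozygote contributes half a homozygote contrast.
    """
    X = np.asarray(dosages, dtype=float)
    if np.isnan(X).any():
        raise ValueError("modified Rogers' distance requires imputed (no-missing) dosages")
    p = X.shape[1]
    D = squareform(pdist(X, metric="euclidean")) / (2.0 * np.sqrt(p))
    return D


def ld_r2_profile(
    panel: GenotypePanel,
    max_dist_bp: int,
    n_bins: int = 20,
) -> tuple[pd.DataFrame, float]:
    """Decay of linkage disequilibrium (squared dosage correlation) with distance.

    Returns a table of (bin midpoint bp, mean r^2, n pairs) over all
    intra-chromosomal SNP pairs closer than ``max_dist_bp``, and the mean
    r^2 between physically adjacent SNPs.
    """
    dist_all: list[np.ndarray] = []
    r2_all: list[np.ndarray] = []
    adj_r2: list[np.ndarray] = []
    chroms = panel.snp_map["chrom"].to_numpy()
    pos = panel.snp_map["pos"].to_numpy(dtype=float)
    X = panel.dosages
    for c in np.unique(chroms):
        cols = np.where(chroms == c)[0]
        if cols.size < 2:
            continue
        Xc = X[:, cols]
        # mean-impute so corrcoef ignores missingness structure
        mu = np.nanmean(Xc, axis=0)
        Xc = np.where(np.isnan(Xc), mu, Xc)
        sd = Xc.std(axis=0)
        ok = sd > 0
        Xc, pc = Xc[:, ok], pos[cols][ok]
        if Xc.shape[1] < 2:
            continue
        R = np.corrcoef(Xc.T)
        r2 = R**2
        iu = np.triu_indices(len(pc), k=1)
        d = np.abs(pc[iu[1]] - pc[iu[0]])
        within = d <= max_dist_bp
        dist_all.append(d[within])
        r2_all.append(r2[iu][within])
        adj_r2.append(np.diag(r2, k=1))
    if not dist_all:
        raise ValueError("need at least 2 SNPs on some chromosome")
    d = np.concatenate(dist_all)
    r2 = np.concatenate(r2_all)
    edges = np.linspace(0, max_dist_bp, n_bins + 1)
    idx = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    rows = []
    for b in range(n_bins):
        sel = idx == b
        if sel.any():
            rows.append(
                {
                    "dist_bp": (edges[b] + edges[b + 1]) / 2.0,
                    "mean_r2": float(r2[sel].mean()),
                    "n_pairs": int(sel.sum()),
                }
            )
    mean_adjacent = float(np.concatenate(adj_r2).mean())
    return pd.DataFrame(rows), mean_adjacent


# ---------------------------------------------------------------------------
# File readers / writers (TSV as written by the simulator, plus VCF)
# ---------------------------------------------------------------------------

def read_genotype_tsv(
    genotype_path: str | Path,
    map_path: str | Path,
    check_replicate_groups: dict[str, list[str]] | None = None,
) -> GenotypePanel:
    """Read a dosage matrix TSV (rows=lines, columns=SNPs, NA=missing) + SNP map."""
    geno = pd.read_csv(genotype_path, sep="\t", index_col=0, comment="#")
    snp_map = pd.read_csv(map_path, sep="\t", comment="#")
    snp_map = snp_map.rename(columns={"pos_bp": "pos"})
    geno = geno[snp_map["snp_id"].tolist()]
    return GenotypePanel(
        dosages=geno.to_numpy(dtype=float),
        line_ids=[str(i) for i in geno.index],
        snp_map=snp_map[["snp_id", "chrom", "pos"]],
        check_replicate_groups=check_replicate_groups,
    )


def read_phenotype_tsv(path: str | Path) -> list[TraitRecord]:
    """Read a long-format phenotype TSV (line_id, trait, value, h2)."""
    df = pd.read_csv(path, sep="\t", comment="#")
    records = []
    for trait, sub in df.groupby("trait", sort=True):
        h2 = float(sub["h2"].iloc[0])
        records.append(
            TraitRecord(
                trait=str(trait),
                line_ids=[str(i) for i in sub["line_id"]],
                values=sub["value"].to_numpy(dtype=float),
                h2=h2,
            )
        )
    return records


def read_vcf(path: str | Path) -> GenotypePanel:
    """Read biallelic SNPs from a VCF into a dosage panel (GT -> ALT count)."""
    from cyvcf2 import VCF  # optional dependency

    vcf = VCF(str(path))
    line_ids = list(vcf.samples)
    rows, snps = [], []
    for var in vcf:
        if len(var.ALT) != 1 or not var.is_snp:
            continue
        gts = np.asarray(var.gt_types, dtype=float)  # 0=hom-ref,1=het,2=unknown,3=hom-alt
        dos = np.select([gts == 0, gts == 1, gts == 3], [0.0, 1.0, 2.0], default=np.nan)
        rows.append(dos)
        snps.append((var.ID or f"{var.CHROM}_{var.POS}", int(var.CHROM), int(var.POS)))
    if not rows:
        raise PanelError("no biallelic SNPs found in VCF")
    snp_map = pd.DataFrame(snps, columns=["snp_id", "chrom", "pos"])
    order = np.lexsort((snp_map["pos"], snp_map["chrom"]))
    return GenotypePanel(
        dosages=np.column_stack([rows[i] for i in order]),
        line_ids=line_ids,
        snp_map=snp_map.iloc[order].reset_index(drop=True),
    )


def write_genotype_tsv(panel: GenotypePanel, genotype_path: str | Path, map_path: str | Path) -> None:
    df = pd.DataFrame(panel.dosages, index=panel.line_ids, columns=panel.snp_map["snp_id"])
    df.index.name = "line_id"
    df.to_csv(genotype_path, sep="\t", na_rep="NA", float_format="%.0f")
    out_map = panel.snp_map.rename(columns={"pos": "pos_bp"})
    out_map.to_csv(map_path, sep="\t", index=False)


def write_kernel_tsv(kernel: KernelMatrix, path: str | Path) -> None:
    df = pd.DataFrame(kernel.values, index=kernel.line_ids, columns=kernel.line_ids)
    df.index.name = "line_id"
    df.to_csv(path, sep="\t", float_format="%.10g")
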