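# Methods

## Scope

`wgpkit` compares five whole-genome prediction (WGP) models with
contrasting assumptions about the distribution of SNP effects, partitions
the genetic variance of a trait across the ten chromosomes of a maize-like
genome, and evaluates everything with a repeated cross-validation protocol
whose accuracy statistic corrects predictive ability for heritability. A
synthetic-data module generates inbred-line panels with controlled linkage
disequilibrium (LD) and trait architecture so that every stage has a known
ground truth.

## The regression set-up

All effect-based models start from

    y = 1 mu + Z u + e,        e ~ N(0, I sigma2_e)

where `y` holds the genotypic means of n inbred lines, `Z` is the n x p
matrix of column-standardized minor-allele dosages and `u` the SNP
effects. Dosages are standardized with the population denominator
(divide by n), which makes the mean diagonal of G = ZZ'/p exactly 1.

**RR-BLUP.** Homogeneous ridge shrinkage with lam_RR = sigma2_e/sigma2_u
estimated by REML on the equivalent genotype-effect model
y = 1 mu + g + e with var(g) = G sigma2_g and G = ZZ'/p. The fit happens
entirely in the n-dimensional kernel space (one eigendecomposition of G,
then a 1-D profile of the restricted likelihood over the variance ratio);
SNP effects are recovered through u = sigma2_u Z' V^-1 (y - mu), which is
the numerically stable form of the back-transformation u = Z'G^-1 g / p
and reproduces the primal closed form (Z'Z + lam I)^-1 Z'(y - mu) to
machine precision (verified in the tests against that closed form).

**LASSO and elastic net.** The glmnet objective convention is used:
(1/(2n))·RSS + lam·(alpha·||u||_1 + (1-alpha)/2·||u||_2²), solved by
cyclic coordinate descent (scikit-learn backend). The penalty weight is
chosen by 5-fold cross-validated MSE *inside the training set*: raw
training MSE would always pick lam -> 0, so "lowest MSE in the training
population" is implemented as inner CV. The lambda path has 50 points by
default (15-30 in the heavy simulation suites) descending geometrically
from lam_max to 0.01·lam_max when p > n (1e-3·lam_max otherwise),
mirroring glmnet's path-depth rule. Ties in the CV curve break toward
larger lambda, then larger alpha — the sparser model. Every returned
solution is checked against the elastic-net KKT conditions; small
instances are verified against an exact sign-pattern enumeration oracle.

**RKHS regression.** The inner-product kernel is replaced by a Gaussian
kernel K_ij = exp(-GD_ij/theta²) on the modified Rogers' distance
GD_ij = sqrt(sum_k (x_ik - x_jk)² / (4p)), scaled so the maximal
biallelic contrast maps to 1 and a heterozygote contributes half. The
bandwidth theta is chosen on a 30-point log-spaced grid over [0.1, 100]
by the REML profile likelihood; kernels that are numerically singular are
repaired to positive definiteness first. Prediction for new lines uses
the cross-kernel rows against stored training weights
sigma2_g V^-1 (y - mu).

**BayesB.** SNP effects have a point mass at zero (probability Pi_u) and
otherwise a normal prior whose per-SNP variance follows a scaled inverse
chi-square, making the marginal effect distribution t with a spike. The
hyperpriors are Pi_u ~ Beta(7, 3), nu_u ~ Gamma(k=5, theta=2),
S²_u ~ Gamma(k=0.1, theta=10), and sigma2_e ~ scaled-inv-chi²(nu_e=4.001,
S²_e) with S²_e = sigma2_e_hat (nu_e-2)/nu_e anchored at the REML
estimate from the ridge model. The scaled-inverse-chi-square uses the
(nu, S²) convention with density ∝ x^-(nu/2+1) exp(-nu S²/(2x)).
Per sweep each SNP receives a joint update: the inclusion indicator is
drawn with the effect integrated out analytically, the effect (if
included) from its conjugate normal conditional, and the effect variance
from its scaled-inv-chi² conditional (a fresh prior draw when excluded,
so the hyperparameter update conditions on included variances only).
Pi_u has a Beta full conditional; nu_u and S²_u move by random-walk
Metropolis on the log scale with step sizes adapted during burn-in toward
30% acceptance. The default protocol is 50,000 iterations, 5,000 burn-in,
thinning 10, with an optional reduction to 5,000 markers evenly spaced by
map position; the test and acceptance suites run shorter chains at
smaller p. With the point mass disabled and a fixed common effect
variance the sampler collapses to a conjugate Bayesian ridge, and its
posterior means are checked against the analytic solution within
Monte-Carlo error (effective sample size conservatively taken as
n_kept/10).

## Genome partitioning

The partition model estimates, simultaneously by REML, one random
genotypic effect per chromosome:

    y = 1 mu + Q b + sum_c g_c + e,   g_c ~ N(0, G_c sigma2_gc)

with G_c = Z_c Z_c'/p_c and Q the first ten principal components of Z
(computed from all post-QC SNPs) absorbing population structure. The
share of chromosome c is sigma2_gc / (sum_c sigma2_gc + sigma2_e).
Chromosome kernels at desk-scale SNP counts are frequently numerically
singular; they are repaired with Higham's alternating-projection nearest
positive-semidefinite algorithm plus a 1e-8 eigenvalue floor whenever
their smallest eigenvalue falls below 1e-8.

The REML fitter runs EM warm-up iterations followed by
average-information steps, with step-halving on the restricted likelihood
and an active set that pins components at zero when updates go negative
(re-entry when the score turns positive). Convergence is |delta logL| <
1e-6 (200 iterations maximum; non-convergence flags the result instead of
raising). On single-kernel problems the fitter agrees with a generic
direct maximizer of the restricted likelihood to better than 1e-4
relative error.

The supporting GWA scan estimates the null-model variance components once
(y = 1 mu + Qb + g + e with the whole-genome kernel) and reuses them for
every SNP's generalized-least-squares Wald test — the standard two-step
approximation; per-SNP full REML would be prohibitive and changes little
at these sample sizes. A SNP's "explained genetic variance" is its
squared correlation with the trait divided by h²; this is the simplest
estimator consistent with converting a phenotype-level R² to a fraction
of genetic variance.

## Cross-validation protocol

Lines are split into 5 disjoint folds of sizes differing by at most one;
the split is repeated 20 times for 100 (fold, repeat) runs. For each run
the model — including imputation and standardization statistics, REML
variance components, and all penalty/bandwidth selection — is fitted
strictly inside the four training folds and scored on the held-out fold.
Predictive ability is Pearson r(y, y_hat) per run; prediction accuracy is
r(g, g_hat) = mean r / h with h the square root of the line-mean
heritability (for synthetic traits, the realized h² recorded by the
generator). Runs with constant predictions (undefined correlation) score
r = 0 with a warning rather than being dropped, so all models are
compared on identical runs. The per-run table is always written, so the
alternative accuracy (average of per-run r/h) can be recomputed from the
output.

## Synthetic data

**Genotypes.** Each chromosome draws SNP positions uniformly, assigns
target minor-allele frequencies from `maf_range` (default U(0.05, 0.5)),
and builds 20 founder haplotypes from an AR(1) latent Gaussian process
thresholded at each frequency; every inbred line is a Markov mosaic of
founder segments, with switch probability 1 - exp(-d/L) between adjacent
SNPs at distance d. A small per-entry allele-redraw probability (0.06)
attenuates short-range LD toward realistic levels. The shared length
scale L = 2.9 x `ld_decay_bp` and the redraw rate were calibrated once so
that the generated panels show a mean adjacent-SNP r² near 0.34 at ~55 kb
spacing and r² ≈ 0.1 at the configured decay distance (500 kb by
default) — the two LD summaries that characterize elite maize diversity
panels. Defaults are 300 lines and ~5,000 SNPs on 10 chromosomes whose
lengths are proportional to the real maize karyotype but scaled to a
~275 Mb genome, which preserves the marker-density-to-LD ratio of a
56K-chip panel at desk scale. Heterozygous calls (`het_rate`) and missing
calls (`missing_rate`) are injected only after the trait is simulated, so
recorded truth is unaffected.

**Traits.** The polygenic architecture draws i.i.d. normal effects at
*every* SNP — the infinitesimal model. The major-QTL architecture adds
one SNP (chosen on the target chromosome with MAF nearest 0.3) whose
effect is solved by root finding so that its squared correlation with the
total genetic value equals `qtl_variance_fraction` exactly; the `mixed`
architecture spreads that fraction over five medium QTL. The residual is
drawn, orthogonalized against the genetic values and rescaled so the
realized line-mean h² equals the request exactly — no iterative tuning.
Per-chromosome genetic-variance fractions are defined as
cov(g_c, g)/var(g), which sums to 1 by construction.

## Problem sizes in the test and acceptance suites

The full protocol of the method (20 CV repeats, 50,000 BayesB iterations,
38K SNPs) is available through the API and config, but the automated
suites run desk-scale versions chosen to keep the whole run in the tens
of minutes: the model-ranking experiment uses 20 simulated traits per
architecture at n=300, p≈5,000 with 5-fold single-repeat CV, a two-point
alpha grid {0.5, 1} and a 15-point lambda path; the partition-recovery
experiment uses 20 replicates; BayesB correctness runs 10,000 iterations
on 50-SNP instances and is excluded from the ranking suite. The
acceptance script reduces the comparison to 8 traits per architecture
(`--n-comparison-traits` restores any size).

## Known limitations

- **Sparse-model accuracy under the infinitesimal architecture.** With
  every SNP causal and only a few dozen independent LD segments per
  desk-scale chromosome, LASSO can tag only a small fraction of the
  genetic variance, so its polygenic-trait accuracy sits far below
  RR-BLUP's — a larger gap than the 0.05-0.14 range typical of real
  maize panels, where long-range, structure-driven LD lets sparse
  markers tag much more variance. That this is intrinsic to the sparse
  model rather than a lambda-selection artifact is quantified by the
  acceptance script (`lasso_oracle_lambda_accuracy_polygenic`: the best
  accuracy achievable anywhere on the path with an oracle lambda, to be
  compared with `accuracy_rrblup_polygenic`). The ranking direction
  (RR-BLUP ≥ LASSO on polygenic traits, sparse models ≥ RR-BLUP with a
  major QTL, RKHS ≈ RR-BLUP) reproduces robustly; the gap magnitude does
  not transfer from desk scale to real data.
- **Null noise of chromosome shares.** Preserving chip-like adjacent-SNP
  r² at 5,000 SNPs compresses chromosomes to a few dozen independent
  segments, so the zero-truncated REML share of a chromosome retains
  half-normal sampling noise under a pure-noise trait (largest for the
  longest chromosome; reported by the acceptance script as
  `partition_null_max_mean_share`). On full-length chromosomes (hundreds
  of segments) null shares concentrate much closer to zero. This is a
  property of the REML estimator at this effective rank, not of the
  optimizer: the fits are kernel-order invariant and match a multi-start
  direct maximizer of the restricted likelihood.
- The generator has no population substructure, no allele-frequency
  spectrum realism, no dominance or epistasis (inbred lines), and
  independent chromosomes — passing tests show the machinery is correct
  under controlled conditions, not that real-data accuracies will match.
- The GWA scan's two-step approximation slightly miscalibrates p-values
  when a single SNP explains a large variance fraction (the null-model
  variance components absorb it); for QTL localization this is
  immaterial.
- RKHS cross-kernel predictions use the analytic Gaussian kernel formula
  against held-out lines even when the training kernel needed a PD
  repair; the discrepancy is bounded by the repair magnitude (~1e-8).
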