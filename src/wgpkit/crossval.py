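"""Repeated k-fold cross-validation of the prediction models.

The protocol partitions the lines into 5 disjoint, size-balanced folds,
repeats the partition 20 times, and evaluates each model on every (fold,
repeat) unit — 100 runs. The per-run predictive ability is the Pearson
correlation r(y, y_hat) between observed and predicted genotypic means in
the held-out fold; the prediction accuracy divides the mean predictive
ability by h, the square root of the trait's line-mean heritability (or
repeatability), estimating the correlation with the unobserved true
genetic values: r(g, g_hat) = r(y, y_hat) / h.

All training happens strictly inside the training folds: imputation and
standardization statistics, REML variance components, penalty and
bandwidth selection are all re-estimated per run and never see the
held-out lines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace as _dc_replace

import numpy as np
import pandas as pd

from .genotypes import GenotypePanel, TraitRecord, impute_and_standardize
from .models import (
    McmcSettings,
    fit_bayesb,
    fit_elastic_net,
    fit_lasso,
    fit_rkhs,
    fit_rrblup,
    predict,
)

__all__ = ["CVPlan", "CVResult", "make_cv_plan", "run_cv", "summarize_comparison"]


@dataclass
class CVPlan:
    """Per-repeat random balanced fold assignments, deterministic in seed."""

    n_folds: int
    n_repeats: int
    seed: int
    fold_assignments: list[dict[str, int]]  # per repeat: line_id -> fold

    @property
    def n_runs(self) -> int:
        return self.n_folds * self.n_repeats

    def split(self, repeat: int, fold: int, line_ids: list[str]):
        assign = self.fold_assignments[repeat]
        test = [lid for lid in line_ids if assign[lid] == fold]
        train = [lid for lid in line_ids if assign[lid] != fold]
        return train, test


def make_cv_plan(
    line_ids: list[str], n_folds: int = 5, n_repeats: int = 20, seed: int = 0
) -> CVPlan:
    """Random balanced partition of lines into folds, repeated."""
    n = len(line_ids)
    if n < n_folds:
        raise ValueError(f"cannot split {n} lines into {n_folds} folds")
    rng = np.random.default_rng(seed)
    assignments = []
    base = np.arange(n) % n_folds  # sizes differ by at most one
    for _ in range(n_repeats):
        perm = rng.permutation(n)
        folds = np.empty(n, dtype=int)
        folds[perm] = base
        assignments.append({lid: int(f) for lid, f in zip(line_ids, folds)})
    return CVPlan(n_folds=n_folds, n_repeats=n_repeats, seed=seed,
                  fold_assignments=assignments)


@dataclass
class CVResult:
    model: str
    trait: str
    per_run: pd.DataFrame  # repeat, fold, r
    mean_r: float
    sd_r: float
    h: float
    accuracy: float
    n_warnings: int = 0

    @property
    def sd_accuracy(self) -> float:
        """Standard deviation of the per-run accuracies r / h."""
        return float(self.per_run["r"].std(ddof=1) / self.h)


def _subset_rows(panel: GenotypePanel, line_ids: list[str]) -> GenotypePanel:
    idx = {lid: i for i, lid in enumerate(panel.line_ids)}
    rows = [idx[lid] for lid in line_ids]
    sub = _dc_replace(panel, dosages=panel.dosages[rows], line_ids=list(line_ids))
    clean = getattr(panel, "_truth_dosages", None)
    if clean is not None:
        sub._truth_dosages = clean[rows]
    return sub


def _drop_monomorphic(panel: GenotypePanel) -> GenotypePanel:
    X = panel.dosages
    mn = np.nanmin(X, axis=0)
    mx = np.nanmax(X, axis=0)
    keep = (mx - mn) > 0
    if keep.all():
        return panel
    return panel.subset_snps(keep)


def _fit_one(model_name: str, train_panel: GenotypePanel, y_tr: np.ndarray,
             settings: dict, seed: int):
    if model_name == "rkhs":
        return fit_rkhs(train_panel, y_tr, theta_grid=settings.get("theta_grid"))
    Z = impute_and_standardize(train_panel)
    if model_name == "rrblup":
        return fit_rrblup(Z, y_tr, lambda_rr=settings.get("lambda_rr"))
    if model_name == "lasso":
        kw = {k: v for k, v in settings.items() if k != "seed"}
        return fit_lasso(Z, y_tr, seed=seed, **kw)
    if model_name == "elastic_net":
        kw = {k: v for k, v in settings.items() if k != "seed"}
        return fit_elastic_net(Z, y_tr, seed=seed, **kw)
    if model_name == "bayesb":
        mc = settings.get("mcmc") or McmcSettings()
        mc = _dc_replace(mc, seed=seed)
        return fit_bayesb(Z, y_tr, mcmc=mc)
    raise ValueError(f"unknown model {model_name!r}")


def run_cv(
    model_name: str,
    panel: GenotypePanel,
    trait: TraitRecord,
    plan: CVPlan,
    model_settings: dict | None = None,
) -> CVResult:
    """Evaluate one model under a CV plan; returns per-run predictive abilities.

    Each run fits the model on the training folds only — including
    imputation/standardization statistics and any hyperparameter selection
    — and scores the held-out fold. Runs whose predictions are constant
    (undefined correlation) score r = 0 with a warning so every model is
    compared on the same set of runs.
    """
    if trait.h2 <= 0:
        raise ValueError("cross-validated accuracy requires h2 > 0")
    settings = dict(model_settings or {})
    y = trait.aligned_to(panel.line_ids)
    y_of = dict(zip(panel.line_ids, y))
    rows = []
    n_warn = 0
    for rep in range(plan.n_repeats):
        for fold in range(plan.n_folds):
            train_ids, test_ids = plan.split(rep, fold, panel.line_ids)
            tr_panel = _drop_monomorphic(_subset_rows(panel, train_ids))
            te_panel = _subset_rows(panel, test_ids)
            y_tr = np.array([y_of[l] for l in train_ids])
            y_te = np.array([y_of[l] for l in test_ids])
            seed = (plan.seed * 1_000 + rep * plan.n_folds + fold) % (2**31 - 1)
            fit = _fit_one(model_name, tr_panel, y_tr, settings, seed)
            y_hat = predict(fit, te_panel)
            if np.std(y_hat) == 0 or np.std(y_te) == 0:
                warnings.warn(
                    f"constant predictions in repeat {rep} fold {fold}; r set to 0"
                )
                r = 0.0
                n_warn += 1
            else:
                r = float(np.corrcoef(y_te, y_hat)[0, 1])
            rows.append({"repeat": rep, "fold": fold, "r": r})
    per_run = pd.DataFrame(rows)
    mean_r = float(per_run["r"].mean())
    sd_r = float(per_run["r"].std(ddof=1)) if len(per_run) > 1 else 0.0
    h = float(np.sqrt(trait.h2))
    return CVResult(
        model=model_name,
        trait=trait.trait,
        per_run=per_run,
        mean_r=mean_r,
        sd_r=sd_r,
        h=h,
        accuracy=mean_r / h,
        n_warnings=n_warn,
    )


def summarize_comparison(results: list[CVResult]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Accuracy table (one row per trait x model) and per-trait accuracy gaps.

    The gap is the max minus min accuracy across models for the same trait
    — the headline statistic for how much the model choice matters.
    """
    if not results:
        raise ValueError("no CV results to summarize")
    rows = [
        {
            "trait": r.trait,
            "h2": r.h**2,
            "model": r.model,
            "accuracy": r.accuracy,
            "sd": r.sd_accuracy,
            "mean_r": r.mean_r,
            "sd_r": r.sd_r,
            "n_runs": len(r.per_run),
        }
        for r in results
    ]
    table = pd.DataFrame(rows).sort_values(["trait", "model"]).reset_index(drop=True)
    gaps = (
        table.groupby("trait")["accuracy"]
        .agg(max_accuracy="max", min_accuracy="min")
        .assign(gap=lambda d: d["max_accuracy"] - d["min_accuracy"])
        .reset_index()
    )
    return table, gaps
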