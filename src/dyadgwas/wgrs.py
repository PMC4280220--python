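"""Repeated cross-validated weighted genetic risk scores (WGRS).

A person's WGRS is the sum over a fixed SNP set of their risk-allele
count times the allele's log-odds effect size.  To keep the weights
honest, each replicate partitions the sample into 10 stratified folds,
estimates weights by multivariable logistic regression on 9 folds, and
scores the held-out fold; pooled validation scores are then categorized
by the quartiles of the control scores and a logistic model of case
status on quartile indicators (adjusted for infant sex and admixture
PCs) yields quartile odds ratios, a 3-df global test and an ROC AUC.
Replicates are repeated (default 1000) and summarized by the mean
log-OR / mean AUC with percentile confidence intervals.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .assoc import fit_logistic
from .geno_io import GenotypeDataset

__all__ = [
    "RiskScoreModel",
    "RiskScoreSummary",
    "compute_score",
    "roc_auc",
    "train_fold_model",
    "cross_validated_scores",
    "crossval_wgrs",
]


@dataclass
class RiskScoreModel:
    """Training-fold weights and risk-allele orientations for a SNP set.

    ``risk_is_minor[j]`` says whether the risk allele at SNP j is the
    stored (minor) dosage allele; weights are the absolute training
    log-ORs, so every weight is non-negative.  ``mean_dosage`` holds the
    training-fold means used to fill missing genotypes at scoring time.
    """

    variant_ids: list[str]
    weights: np.ndarray
    risk_is_minor: np.ndarray
    mean_dosage: np.ndarray
    fold_id: int = -1


@dataclass
class RiskScoreSummary:
    quartile_or: np.ndarray           # Q2..Q4 point estimates vs Q1
    quartile_ci: np.ndarray           # 3 x 2 percentile bounds
    auc: float
    auc_ci: tuple[float, float]
    global_p_median: float
    n_replicates: int
    replicates: pd.DataFrame = field(repr=False, default=None)

    def to_frame(self) -> pd.DataFrame:
        rows = [{"quartile": 1, "odds_ratio": 1.0, "ci_low": np.nan, "ci_high": np.nan}]
        for i in range(3):
            rows.append({"quartile": i + 2, "odds_ratio": self.quartile_or[i],
                         "ci_low": self.quartile_ci[i, 0],
                         "ci_high": self.quartile_ci[i, 1]})
        return pd.DataFrame(rows)


def compute_score(dosages: np.ndarray, model: RiskScoreModel) -> np.ndarray:
    """WGRS = sum over loci of weight x risk-allele count.

    ``dosages`` has one column per model variant (rows = samples, or a
    single vector for one sample).  Risk-allele count is the dosage when
    the minor allele is the risk allele, else ``2 - dosage``; missing
    entries are replaced by the training-fold mean dosage first.
    """
    d = np.atleast_2d(np.asarray(dosages, float))
    if d.shape[1] != len(model.variant_ids):
        raise ValueError("dosage columns do not match the model's variants")
    d = np.where(np.isnan(d), model.mean_dosage, d)
    counts = np.where(model.risk_is_minor, d, 2.0 - d)
    scores = counts @ model.weights
    return scores if scores.size > 1 else float(scores[0])


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC as the Mann-Whitney U statistic / (n1*n0); ties count 1/2."""
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    n1 = int(labels.sum())
    n0 = labels.size - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("AUC undefined: both classes must be present")
    ranks = stats.rankdata(scores)
    u = ranks[labels == 1].sum() - n1 * (n1 + 1) / 2
    return float(u / (n1 * n0))


def _design_cols(dataset: GenotypeDataset, covariates, pcs):
    cols = []
    if covariates:
        cols += [dataset.covariates[c].to_numpy(float) for c in covariates]
    if pcs is not None:
        cols += [pcs[:, a] for a in range(pcs.shape[1])]
    return cols


def train_fold_model(
    dataset: GenotypeDataset,
    snp_set: Sequence[str],
    train_mask: np.ndarray,
    covariates: Sequence[str] | None = None,
    pcs: np.ndarray | None = None,
    fold_id: int = -1,
) -> RiskScoreModel:
    """Multivariable logistic fit on the training rows -> scoring weights."""
    idx = [dataset.variant_index(s) for s in snp_set]
    X = dataset.dosage[np.ix_(train_mask, idx)]
    mean_d = np.nanmean(X, axis=0)
    X = np.where(np.isnan(X), mean_d, X)
    extra = _design_cols(dataset, covariates, pcs)
    design = np.column_stack([np.ones(X.shape[0]), X]
                             + [c[train_mask] for c in extra])
    fit = fit_logistic(dataset.phenotype[train_mask].astype(float), design)
    coefs = fit.coef[1:1 + len(idx)]
    coefs = np.where(np.isfinite(coefs), coefs, 0.0)
    return RiskScoreModel(
        variant_ids=list(snp_set),
        weights=np.abs(coefs),
        risk_is_minor=coefs > 0,
        mean_dosage=mean_d,
        fold_id=fold_id,
    )


def _stratified_folds(phenotype, folds, rng):
    assign = np.empty(phenotype.size, int)
    for cls in (0, 1):
        rows = np.flatnonzero(phenotype == cls)
        rng.shuffle(rows)
        assign[rows] = np.arange(rows.size) % folds
    return assign


def cross_validated_scores(
    dataset: GenotypeDataset,
    snp_set: Sequence[str],
    fold_assign: np.ndarray,
    covariates: Sequence[str] | None = None,
    pcs: np.ndarray | None = None,
) -> np.ndarray:
    """Out-of-fold WGRS for every sample under a fixed partition.

    Each sample's score comes only from the model trained with its fold
    held out, so no label leaks into its own score.
    """
    idx = [dataset.variant_index(s) for s in snp_set]
    scores = np.empty(dataset.n_samples)
    for f in np.unique(fold_assign):
        train = fold_assign != f
        model = train_fold_model(dataset, snp_set, train, covariates, pcs, fold_id=int(f))
        scores[~train] = compute_score(dataset.dosage[np.ix_(~train, idx)], model)
    return scores


def _quartile_assign(scores, control_scores):
    cuts = np.quantile(control_scores, [0.25, 0.5, 0.75], method="lower")
    return np.searchsorted(cuts, scores, side="left")  # 0..3; ties go down


def crossval_wgrs(
    dataset: GenotypeDataset,
    snp_set: Sequence[str],
    covariates: Sequence[str] | None = ("sex",),
    pcs: np.ndarray | None = None,
    folds: int = 10,
    repeats: int = 1000,
    seed: int = 0,
) -> RiskScoreSummary:
    """Repeated stratified 10-fold cross-validated WGRS with quartile ORs.

    Per replicate: stratified partition, per-fold training weights and
    validation scores, quartile cut-points from the pooled control
    scores, adjusted quartile ORs vs quartile 1 with a 3-df global LRT,
    and the ROC AUC.  The summary exponentiates the mean replicate
    log-ORs and reports 2.5-97.5 percentile intervals across replicates.
    """
    y = dataset.phenotype.astype(float)
    extra = _design_cols(dataset, covariates, pcs)
    rows = []
    for rep in range(repeats):
        rng = np.random.default_rng([seed, rep])
        for attempt in range(10):
            assign = _stratified_folds(dataset.phenotype, folds, rng)
            if all(len(np.unique(dataset.phenotype[assign != f])) == 2
                   for f in range(folds)):
                break
        else:
            raise RuntimeError("could not build folds containing both classes")
        scores = cross_validated_scores(dataset, snp_set, assign, covariates, pcs)
        quart = _quartile_assign(scores, scores[dataset.phenotype == 0])
        Q = np.column_stack([(quart == k).astype(float) for k in (1, 2, 3)])
        base_cols = [np.ones(dataset.n_samples)] + extra
        full = np.column_stack(base_cols + [Q])
        fit_full = fit_logistic(y, full)
        fit_null = fit_logistic(y, np.column_stack(base_cols))
        lrt = max(0.0, 2 * (fit_full.loglik - fit_null.loglik))
        global_p = float(stats.chi2.sf(lrt, df=3))
        k0 = len(base_cols)
        logors = fit_full.coef[k0:k0 + 3]
        ses = fit_full.se[k0:k0 + 3]
        rows.append({
            "replicate": rep,
            "logor_q2": logors[0], "logor_q3": logors[1], "logor_q4": logors[2],
            "se_q2": ses[0], "se_q3": ses[1], "se_q4": ses[2],
            "auc": roc_auc(scores, dataset.phenotype),
            "global_p": global_p,
        })
    reps = pd.DataFrame(rows)
    logor = reps[["logor_q2", "logor_q3", "logor_q4"]].to_numpy()
    point = np.exp(logor.mean(axis=0))
    ci = np.exp(np.percentile(logor, [2.5, 97.5], axis=0).T)
    auc = reps["auc"].to_numpy()
    return RiskScoreSummary(
        quartile_or=point,
        quartile_ci=ci,
        auc=float(auc.mean()),
        auc_ci=(float(np.percentile(auc, 2.5)), float(np.percentile(auc, 97.5))),
        global_p_median=float(reps["global_p"].median()),
        n_replicates=repeats,
        replicates=reps,
    )
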