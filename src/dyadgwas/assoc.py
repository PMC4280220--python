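"""Per-SNP logistic association, FDR, genomic inflation, and PCA.

The scan fits, for each SNP, an additive logistic model of case status
on minor-allele dosage plus an intercept, optional covariates and the
top principal components, dropping samples with a missing genotype at
that SNP.  Wald statistics give the odds ratio, 95% CI and two-sided
p-value; Benjamini-Hochberg adjustment gives q-values, and the genomic
inflation factor summarizes departure of the median test statistic from
its null expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .geno_io import GenotypeDataset, Variant

__all__ = [
    "LogisticFit",
    "AssocRecord",
    "ScanSummary",
    "PCScores",
    "fit_logistic",
    "association_scan",
    "bh_fdr",
    "genomic_inflation",
    "compute_pcs",
    "welch_ttest_summary",
    "chisq_counts",
    "two_group_tests",
]

#: Median of the 1-df chi-square distribution.
CHI2_1DF_MEDIAN = 0.454936


@dataclass
class LogisticFit:
    coef: np.ndarray
    se: np.ndarray
    loglik: float
    converged: bool
    separated: bool = False
    n_iter: int = 0


def fit_logistic(
    y: np.ndarray, X: np.ndarray, max_iter: int = 50, tol: float = 1e-8
) -> LogisticFit:
    """Logistic MLE by iteratively reweighted least squares (Newton).

    Converges when the largest coefficient change drops below ``tol``.
    Perfect or quasi-perfect separation is flagged (diverging
    coefficients) rather than raised; standard errors come from the
    observed information matrix.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, k = X.shape
    if n <= k:
        raise ValueError("need more observations than parameters")
    beta = np.zeros(k)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        eta = np.clip(X @ beta, -30, 30)
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        XtW = X.T * w
        info = XtW @ X
        grad = X.T @ (y - p)
        try:
            step = np.linalg.solve(info + 1e-10 * np.eye(k), grad)
        except np.linalg.LinAlgError:
            break
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            converged = True
            break
    eta = np.clip(X @ beta, -30, 30)
    p = 1.0 / (1.0 + np.exp(-eta))
    loglik = float(np.sum(y * np.log(np.clip(p, 1e-300, 1))
                          + (1 - y) * np.log(np.clip(1 - p, 1e-300, 1))))
    w = p * (1.0 - p)
    info = (X.T * w) @ X
    separated = (not converged) and bool(np.max(np.abs(beta)) > 15)
    try:
        cov = np.linalg.inv(info + 1e-10 * np.eye(k))
        se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except np.linalg.LinAlgError:
        se = np.full(k, np.inf)
    if separated:
        se = np.full(k, np.inf)
    return LogisticFit(beta, se, loglik, converged, separated, it)


@dataclass
class AssocRecord:
    variant: Variant
    maf_controls: float
    odds_ratio: float
    ci95: tuple[float, float]
    p_value: float
    q_value: float = np.nan
    n_used: int = 0
    flag: str | None = None  # None | "monomorphic" | "separation"


@dataclass
class ScanSummary:
    n_tests: int
    lambda_gc: float
    qq_expected: np.ndarray
    qq_observed: np.ndarray


@dataclass
class PCScores:
    """Principal-component scores on the standardized dosage matrix."""

    scores: np.ndarray  # n_samples x k
    explained_variance_fraction: np.ndarray


def bh_fdr(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in input order, capped at 1."""
    p = np.asarray(p_values, float)
    if p.size == 0:
        return p.copy()
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def genomic_inflation(p_values: np.ndarray) -> float:
    """lambda_GC: median 1-df chi-square statistic / its null median."""
    p = np.asarray(p_values, float)
    chi2 = stats.chi2.isf(p, df=1)
    return float(np.median(chi2) / CHI2_1DF_MEDIAN)


def compute_pcs(dataset: GenotypeDataset, k: int) -> PCScores:
    """Top-k PCA of the standardized dosage matrix.

    Dosages are mean-imputed per SNP, centered at twice the allele
    frequency and scaled by the binomial standard deviation
    ``sqrt(2 p (1-p))``; zero-variance SNPs are skipped.
    """
    d = dataset.dosage
    n, m = d.shape
    if not k < min(n, m):
        raise ValueError("k must be smaller than both sample and SNP counts")
    mean = np.nanmean(d, axis=0)
    filled = np.where(np.isnan(d), mean, d)
    phat = mean / 2.0
    scale = np.sqrt(2.0 * phat * (1.0 - phat))
    keep = scale > 0
    Z = (filled[:, keep] - 2.0 * phat[keep]) / scale[keep]
    U, S, _ = np.linalg.svd(Z, full_matrices=False)
    var = S**2
    return PCScores(U[:, :k] * S[:k], var[:k] / var.sum())


def _maf_controls(dataset: GenotypeDataset, j: int) -> float:
    col = dataset.dosage[dataset.phenotype == 0, j]
    col = col[~np.isnan(col)]
    if col.size == 0:
        return np.nan
    f = col.sum() / (2 * col.size)
    return float(min(f, 1 - f))


def association_scan(
    dataset: GenotypeDataset,
    covariates: list[str] | None = None,
    pcs: PCScores | None = None,
    k_pcs: int = 4,
) -> tuple[list[AssocRecord], ScanSummary]:
    """Per-SNP additive logistic scan with covariate/PC adjustment.

    Returns records sorted by ascending p-value plus a summary with the
    genomic inflation factor and QQ coordinates.  Monomorphic-after-drop
    SNPs and separated fits are flagged, not dropped silently.
    """
    y_all = dataset.phenotype.astype(float)
    cov_cols = []
    if covariates:
        for c in covariates:
            cov_cols.append(dataset.covariates[c].to_numpy(float))
    if pcs is not None:
        for a in range(min(k_pcs, pcs.scores.shape[1])):
            cov_cols.append(pcs.scores[:, a])
    base = np.column_stack([np.ones(dataset.n_samples)] + cov_cols)

    records: list[AssocRecord] = []
    for j, v in enumerate(dataset.variants):
        dose = dataset.dosage[:, j]
        use = ~np.isnan(dose)
        maf = _maf_controls(dataset, j)
        rec = AssocRecord(v, maf, np.nan, (np.nan, np.nan), np.nan, n_used=int(use.sum()))
        x = dose[use]
        if x.size == 0 or np.all(x == x[0]):
            rec.flag = "monomorphic"
            records.append(rec)
            continue
        X = np.column_stack([base[use], x])
        fit = fit_logistic(y_all[use], X)
        b, se = fit.coef[-1], fit.se[-1]
        if fit.separated or not np.isfinite(se) or se == 0:
            rec.flag = "separation"
            rec.odds_ratio = np.inf if b > 0 else 0.0
            records.append(rec)
            continue
        z = b / se
        rec.odds_ratio = float(np.exp(b))
        rec.ci95 = (float(np.exp(b - 1.96 * se)), float(np.exp(b + 1.96 * se)))
        rec.p_value = float(2 * stats.norm.sf(abs(z)))
        records.append(rec)

    tested = [r for r in records if np.isfinite(r.p_value)]
    pvals = np.array([r.p_value for r in tested])
    qvals = bh_fdr(pvals)
    for r, qv in zip(tested, qvals):
        r.q_value = float(qv)
    records.sort(key=lambda r: r.p_value if np.isfinite(r.p_value) else np.inf)

    lam = genomic_inflation(pvals) if pvals.size else np.nan
    obs = -np.log10(np.sort(pvals)) if pvals.size else np.array([])
    exp = -np.log10((np.arange(1, pvals.size + 1) - 0.5) / pvals.size) if pvals.size else np.array([])
    summary = ScanSummary(len(tested), lam, exp[::-1] if exp.size else exp, obs[::-1] if obs.size else obs)
    return records, summary


def records_to_frame(records: list[AssocRecord]) -> pd.DataFrame:
    """Scan results as a table mirroring the usual top-hits layout."""
    return pd.DataFrame({
        "gene": [r.variant.gene for r in records],
        "snp": [r.variant.id for r in records],
        "minor_allele": [r.variant.allele_minor for r in records],
        "maf_controls": [r.maf_controls for r in records],
        "odds_ratio": [r.odds_ratio for r in records],
        "ci_low": [r.ci95[0] for r in records],
        "ci_high": [r.ci95[1] for r in records],
        "p_value": [r.p_value for r in records],
        "q_value": [r.q_value for r in records],
        "flag": [r.flag for r in records],
    })


# ---------------------------------------------------------------------------
# Baseline group comparisons (case vs control characteristics)


def welch_ttest_summary(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> tuple[float, float]:
    """Welch two-sample t-test from group summary statistics."""
    res = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2, equal_var=False)
    return float(res.statistic), float(res.pvalue)


def chisq_counts(counts: np.ndarray) -> tuple[float, float]:
    """Pearson chi-square on a 2 x k count table, no continuity correction."""
    counts = np.asarray(counts, float)
    if counts.sum(axis=1).min() == 0 or counts.sum(axis=0).min() == 0:
        raise ValueError("undefined test: empty row or column")
    res = stats.chi2_contingency(counts, correction=False)
    return float(res[0]), float(res[1])


def two_group_tests(characteristics: list[tuple]) -> pd.DataFrame:
    """Case-vs-control comparisons for a list of characteristics.

    Each entry is ``("continuous", name, (mean, sd, n), (mean, sd, n))``
    (Welch t-test) or ``("categorical", name, counts_2xk)`` (Pearson
    chi-square).  Returns one row per characteristic with the statistic
    and two-sided p-value.
    """
    rows = []
    for entry in characteristics:
        kind, name = entry[0], entry[1]
        if kind == "continuous":
            (m1, s1, n1), (m2, s2, n2) = entry[2], entry[3]
            if s1 == 0 and s2 == 0:
                rows.append({"name": name, "kind": kind, "statistic": np.nan,
                             "p_value": np.nan, "flag": "zero-variance"})
                continue
            t, p = welch_ttest_summary(m1, s1, n1, m2, s2, n2)
            rows.append({"name": name, "kind": kind, "statistic": t,
                         "p_value": p, "flag": None})
        elif kind == "categorical":
            chi2, p = chisq_counts(entry[2])
            rows.append({"name": name, "kind": kind, "statistic": chi2,
                         "p_value": p, "flag": None})
        else:
            raise ValueError(f"unknown characteristic kind {kind!r}")
    return pd.DataFrame(rows)
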