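"""Mother-child dyad multinomial risk models.

A biallelic variant in a mother-child pair yields one of seven
Mendelian-compatible (mother, child) minor-allele dosage cells.  Under
Hardy-Weinberg equilibrium, random mating and a rare disease, the
population distribution over these cells is a simple function of the
risk-allele frequency ``q``, and the distribution among affected
(case) pregnancies is the population distribution re-weighted by a
multiplicative risk model:

    mu(m, c, origin) = S_m * R_c * Im^[c = 1 and maternally derived]
                       * gamma01^[m = 0, c = 1] * gamma21^[m = 2, c = 1]

with ``S_0 = R_0 = 1``.  ``R1, R2`` are fetal-genotype relative risks,
``S1, S2`` maternal-genotype relative risks, ``Im`` a maternal
imprinting multiplier acting when a heterozygous child's risk allele
came from the mother, and ``gamma01, gamma21`` maternal-fetal
incompatibility interaction terms acting when the child carries one
copy while the mother carries zero or two.

Control dyads are modelled with the unconditioned population cell
probabilities (rare-disease approximation).  Model labels fix subsets
of the multipliers at 1:

=========  =============================  ==
label      free multipliers               k
=========  =============================  ==
Null       (none)                         1
F          R1, R2                         3
M          S1, S2                         3
M+F        R1, R2, S1, S2                 5
M+F+Im     R1, R2, S1, S2, Im             6
I          R1, R2, S1, S2, g01, g21       7
=========  =============================  ==

(k counts the allele frequency q plus the free multipliers; BIC uses
``-2*loglik + k*ln(n_dyads)``.)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .geno_io import DYAD_CELLS, DyadDataset

__all__ = [
    "DyadModelParams",
    "DyadModelFit",
    "ModelComparisonTable",
    "MODEL_FREE_PARAMS",
    "dyad_cell_probabilities",
    "sample_dyad_counts",
    "dyad_loglik",
    "fit_dyad_model",
    "likelihood_ratio_test",
    "select_best_model",
    "imprinting_scan",
]

#: Free multiplier names per model label (q is always free).
MODEL_FREE_PARAMS: dict[str, tuple[str, ...]] = {
    "Null": (),
    "F": ("R1", "R2"),
    "M": ("S1", "S2"),
    "M+F": ("R1", "R2", "S1", "S2"),
    "M+F+Im": ("R1", "R2", "S1", "S2", "Im"),
    "I": ("R1", "R2", "S1", "S2", "gamma01", "gamma21"),
}

_MULTIPLIERS = ("R1", "R2", "S1", "S2", "Im", "gamma01", "gamma21")


@dataclass(frozen=True)
class DyadModelParams:
    """Risk-allele frequency and risk multipliers; fixed parameters are 1."""

    q: float
    R1: float = 1.0
    R2: float = 1.0
    S1: float = 1.0
    S2: float = 1.0
    Im: float = 1.0
    gamma01: float = 1.0
    gamma21: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.q < 1.0:
            raise ValueError("q must lie strictly inside (0, 1)")
        for name in _MULTIPLIERS:
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def multiplier(self, m: int, c: int, maternal_origin: bool) -> float:
        """Relative risk mu(m, c, origin) for one transmission outcome."""
        S = (1.0, self.S1, self.S2)
        R = (1.0, self.R1, self.R2)
        mu = S[m] * R[c]
        if c == 1 and maternal_origin:
            mu *= self.Im
        if c == 1 and m == 0:
            mu *= self.gamma01
        if c == 1 and m == 2:
            mu *= self.gamma21
        return mu


@dataclass
class DyadModelFit:
    model: str
    params: DyadModelParams
    loglik: float
    k: int
    bic: float
    converged: bool


@dataclass
class ModelComparisonTable:
    """Ordered nested-model comparisons with the BIC-selected model."""

    rows: pd.DataFrame
    selected_model: str
    fits: dict[str, DyadModelFit] = field(default_factory=dict)


def dyad_cell_probabilities(params: DyadModelParams) -> tuple[np.ndarray, np.ndarray]:
    """Case and control probabilities over the 7 dyad cells.

    Control cells are the HWE/random-mating population duo probabilities;
    case cells re-weight each (cell, parental-origin) configuration by its
    risk multiplier and renormalize.  Both vectors sum to 1.
    """
    q = params.q
    p = 1.0 - q
    # population mass per (cell, origin of a heterozygous child's risk allele)
    # cells with an unambiguous origin carry their full mass on that branch
    pop = np.array([p**3, p*p*q, p*p*q, p*p*q + p*q*q, p*q*q, p*q*q, q**3])
    case = np.empty(7)
    for k, (m, c) in enumerate(DYAD_CELLS):
        if (m, c) == (1, 1):
            case[k] = (p*p*q) * params.multiplier(1, 1, True) \
                    + (p*q*q) * params.multiplier(1, 1, False)
        else:
            # maternal origin iff the mother carries 2 copies (she must
            # transmit the risk allele); m=0 can never transmit it
            maternal = m == 2
            case[k] = pop[k] * params.multiplier(m, c, maternal)
    total = case.sum()
    if total <= 0:
        raise ValueError("degenerate risk model: case probabilities sum to 0")
    return case / total, pop


def sample_dyad_counts(
    params: DyadModelParams,
    n_case: int,
    n_control: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw 7-cell case/control counts directly from the model.

    Multinomial sampling from the analytic conditional cell
    probabilities — the exact distribution of counts obtained by
    individual-level rejection sampling (see
    :func:`dyadgwas.simulate.simulate_dyads`), at a fraction of the
    cost; used for many-replicate calibration studies.
    """
    case_p, control_p = dyad_cell_probabilities(params)
    return (rng.multinomial(n_case, case_p),
            rng.multinomial(n_control, control_p))


def dyad_loglik(
    case_counts: np.ndarray, control_counts: np.ndarray, params: DyadModelParams
) -> float:
    """Multinomial log-likelihood of 7-cell case/control counts."""
    case_p, control_p = dyad_cell_probabilities(params)
    ll = 0.0
    for counts, probs in ((np.asarray(case_counts), case_p), (np.asarray(control_counts), control_p)):
        pos = counts > 0
        if (probs[pos] <= 0).any():
            return -np.inf
        ll += float(np.sum(counts[pos] * np.log(probs[pos])))
    return ll


def _params_from_theta(theta: np.ndarray, free: tuple[str, ...]) -> DyadModelParams:
    q = 1.0 / (1.0 + np.exp(-theta[0]))
    kwargs = {name: float(np.exp(t)) for name, t in zip(free, theta[1:])}
    return DyadModelParams(q=q, **kwargs)


# Origin-resolved transmission configurations: cell index each maps to, and
# the exponent of each multiplier (R1, R2, S1, S2, Im, g01, g21) in mu.
# Rows: (0,0) (0,1) (1,0) (1,1)maternal (1,1)paternal (1,2) (2,1) (2,2)
_CONFIG_CELL = np.array([0, 1, 2, 3, 3, 4, 5, 6])
_CONFIG_EXPONENTS = np.array([
    [0, 0, 0, 0, 0, 0, 0],
    [1, 0, 0, 0, 0, 1, 0],
    [0, 0, 1, 0, 0, 0, 0],
    [1, 0, 1, 0, 1, 0, 0],
    [1, 0, 1, 0, 0, 0, 0],
    [0, 1, 1, 0, 0, 0, 0],
    [1, 0, 0, 1, 1, 0, 1],
    [0, 1, 0, 1, 0, 0, 0],
], dtype=float)


def _fast_nll_factory(case_counts, control_counts, free):
    """Vectorized negative log-likelihood in (logit q, log free multipliers)."""
    free_idx = np.array([_MULTIPLIERS.index(name) for name in free], dtype=int)
    cc = np.asarray(case_counts, float)
    uc = np.asarray(control_counts, float)

    def nll(theta: np.ndarray) -> float:
        q = 1.0 / (1.0 + np.exp(-theta[0]))
        p = 1.0 - q
        if q <= 0.0 or q >= 1.0:
            return np.inf
        logmult = np.zeros(7)
        logmult[free_idx] = theta[1:]
        popw = np.array([p**3, p*p*q, p*p*q, p*p*q, p*q*q, p*q*q, p*q*q, q**3])
        w = popw * np.exp(_CONFIG_EXPONENTS @ logmult)
        case_cells = np.bincount(_CONFIG_CELL, weights=w, minlength=7)
        total = case_cells.sum()
        if not np.isfinite(total) or total <= 0:
            return np.inf
        case_p = case_cells / total
        pop_cells = np.bincount(_CONFIG_CELL, weights=popw, minlength=7)
        with np.errstate(divide="ignore"):
            ll = np.sum(np.where(cc > 0, cc * np.log(case_p), 0.0)) \
               + np.sum(np.where(uc > 0, uc * np.log(pop_cells), 0.0))
        return -ll if np.isfinite(ll) else np.inf

    return nll


def _initial_q(case_counts: np.ndarray, control_counts: np.ndarray) -> float:
    """Moment estimate of q from pooled mother+child allele counts."""
    cells = np.array(DYAD_CELLS)
    alleles = cells.sum(axis=1)
    tot = np.asarray(case_counts) + np.asarray(control_counts)
    n = tot.sum()
    if n == 0:
        return 0.5
    qhat = float((tot * alleles).sum()) / (4.0 * n)
    return min(max(qhat, 0.02), 0.98)


def fit_dyad_model(
    case_counts: np.ndarray,
    control_counts: np.ndarray,
    model: str,
    n_starts: int = 5,
) -> DyadModelFit:
    """Maximum-likelihood fit of one dyad model to 7-cell counts.

    Optimizes over (logit q, log free multipliers) with L-BFGS-B from
    several deterministic perturbed starts around moment-style initials.
    """
    if isinstance(model, tuple):
        free = model  # custom free-multiplier set (e.g. single-multiplier fits)
        model = "+".join(free) if free else "Null"
    elif model in MODEL_FREE_PARAMS:
        free = MODEL_FREE_PARAMS[model]
    else:
        raise ValueError(f"unknown model {model!r}")
    case_counts = np.asarray(case_counts, float)
    control_counts = np.asarray(control_counts, float)
    n_dyads = int(case_counts.sum() + control_counts.sum())
    if n_dyads < 20:
        raise ValueError("need at least 20 dyads to fit a dyad model")

    q0 = _initial_q(case_counts, control_counts)
    base = np.concatenate([[np.log(q0 / (1 - q0))], np.zeros(len(free))])
    nll = _fast_nll_factory(case_counts, control_counts, free)

    rng = np.random.default_rng(12345)  # fixed: multi-starts are part of the algorithm
    best = None
    # bounds keep every probability strictly positive -> finite objective
    bounds = [(-12.0, 12.0)] + [(-8.0, 8.0)] * len(free)
    for s in range(n_starts):
        x0 = base if s == 0 else base + rng.normal(0, 0.5, size=base.size)
        res = optimize.minimize(nll, x0, method="L-BFGS-B", bounds=bounds,
                                options={"maxiter": 500, "ftol": 1e-12, "gtol": 1e-9})
        if best is None or res.fun < best.fun - 1e-12:
            best = res
    assert best is not None
    converged = bool(np.isfinite(best.fun))
    params = _params_from_theta(best.x, free)
    loglik = -float(best.fun)
    k = 1 + len(free)
    bic = -2.0 * loglik + k * np.log(n_dyads)
    return DyadModelFit(model, params, loglik, k, bic, converged)


def likelihood_ratio_test(
    fit_full: DyadModelFit, fit_reduced: DyadModelFit, df: int
) -> tuple[float, float]:
    """LRT statistic 2*(ll_full - ll_reduced) and its chi-square(df) p."""
    stat = 2.0 * (fit_full.loglik - fit_reduced.loglik)
    if stat < -1e-6:
        raise RuntimeError(
            f"negative LRT statistic {stat:.3g}: optimization failure "
            f"({fit_full.model} vs {fit_reduced.model})"
        )
    stat = max(stat, 0.0)
    p = float(stats.chi2.sf(stat, df))
    return stat, p


_COMPARISONS = [
    ("I", "M+F"),
    ("M+F", "F"),
    ("M+F", "M"),
    ("M+F", "Null"),
    ("M", "Null"),
    ("F", "Null"),
    ("Null", None),
]


def select_best_model(
    case_counts: np.ndarray, control_counts: np.ndarray
) -> ModelComparisonTable:
    """Fit Null, F, M, M+F and I and select the smallest-BIC model.

    Emits the fixed seven-row nested-comparison layout (first model's
    log-likelihood, LRT against the second, first model's BIC).
    """
    fits = {m: fit_dyad_model(case_counts, control_counts, m)
            for m in ("Null", "F", "M", "M+F", "I")}
    rows = []
    for full, reduced in _COMPARISONS:
        fa = fits[full]
        if reduced is None:
            rows.append({"comparison": "Model Null", "loglik": fa.loglik,
                         "lrt": np.nan, "lrt_p": np.nan, "bic": fa.bic,
                         "converged": fa.converged})
            continue
        fb = fits[reduced]
        df = fa.k - fb.k
        if fa.converged and fb.converged:
            stat = max(2.0 * (fa.loglik - fb.loglik), 0.0)
            p = float(stats.chi2.sf(stat, df))
        else:
            stat = p = np.nan
        rows.append({"comparison": f"Model {full} vs Model {reduced}",
                     "loglik": fa.loglik, "lrt": stat, "lrt_p": p,
                     "bic": fa.bic, "converged": fa.converged and fb.converged})
    ok = {m: f for m, f in fits.items() if f.converged}
    selected = min(ok, key=lambda m: ok[m].bic)
    return ModelComparisonTable(pd.DataFrame(rows), selected, fits)


def imprinting_scan(
    dyads: DyadDataset, variant_ids: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-variant maternal-imprinting LRT (M+F+Im vs M+F, 1 df).

    Returns one row per analyzable variant with the statistic, asymptotic
    p-value and a ``significant`` flag at 0.05; monomorphic variants are
    skipped with a flag.
    """
    ids = [v.id for v in dyads.variants]
    wanted = set(variant_ids) if variant_ids is not None else None
    rows = []
    for j, v in enumerate(dyads.variants):
        if wanted is not None and v.id not in wanted:
            continue
        cc = dyads.case_counts[j]
        uc = dyads.control_counts[j]
        cells = np.array(DYAD_CELLS)
        alleles = (cells.sum(axis=1) * (cc + uc)).sum()
        total = 4 * (cc + uc).sum()
        if total == 0 or alleles == 0 or alleles == total:
            rows.append({"variant": v.id, "position": v.position_bp, "gene": v.gene,
                         "lrt": np.nan, "p_value": np.nan, "significant": False,
                         "skipped_monomorphic": True})
            continue
        fit_mf = fit_dyad_model(cc, uc, "M+F")
        fit_im = fit_dyad_model(cc, uc, "M+F+Im")
        stat, p = likelihood_ratio_test(fit_im, fit_mf, df=1)
        rows.append({"variant": v.id, "position": v.position_bp, "gene": v.gene,
                     "lrt": stat, "p_value": p, "significant": p < 0.05,
                     "skipped_monomorphic": False})
    return pd.DataFrame(rows)
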