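"""Synthetic case-control genotypes and mother-child dyads.

Emulates the statistical structure the downstream analyses assume:
biallelic SNPs under Hardy-Weinberg equilibrium with a configurable
minor-allele-frequency spectrum and first-order-Markov linkage
disequilibrium, case-control sampling under a multiplicative (logistic)
disease model with optional two-subpopulation stratification, and
mother-child duos under HWE + random mating + rare-disease
multiplicative risks including imprinting and maternal-fetal
incompatibility terms (see :mod:`dyadgwas.dyad_models`).

Everything is reproducible from a single integer seed; all sub-streams
are derived deterministically from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dyad_models import DyadModelParams
from .geno_io import DYAD_CELLS, DyadDataset, GenotypeDataset, Variant

__all__ = [
    "SimulationConfig",
    "simulate_case_control",
    "simulate_population",
    "simulate_dyads",
    "inject_missingness",
]


@dataclass
class SimulationConfig:
    """Study-design and genetic-architecture knobs for the simulators.

    Defaults mirror the study's structure: a few hundred cases and
    controls, ~1% baseline disease risk (the case phenotype complicates
    about 1% of pregnancies), common variants, and a couple of hundred
    dyads per arm.
    """

    n_cases: int = 280
    n_controls: int = 244
    n_case_dyads: int = 222
    n_control_dyads: int = 198
    n_snps: int = 1000
    n_dyad_snps: int | None = None  # variants in the dyad arm; defaults to n_snps
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.0
    causal_effects: list[tuple[int, float]] = field(default_factory=list)
    baseline_risk: float = 0.01
    dyad_params: DyadModelParams = field(default_factory=lambda: DyadModelParams(q=0.3))
    stratification: tuple[float, float] | None = None  # (divergence F, mixing prop)
    missing_rate: float = 0.0
    hwe_violation: tuple[int, float] | None = None  # (snp index, inbreeding f)
    position_spacing_bp: int = 5_000
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must lie within (0, 0.5]")
        if not 0 <= self.ld_rho < 1:
            raise ValueError("ld_rho must be in [0, 1)")
        if not 0 <= self.baseline_risk <= 1:
            raise ValueError("baseline_risk must be a probability")
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be a probability")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")
        for idx, orr in self.causal_effects:
            if orr <= 0:
                raise ValueError("odds ratios must be positive")
            if not 0 <= idx < self.n_snps:
                raise ValueError("causal SNP index out of range")


def _make_variants(n_snps: int, rng: np.random.Generator) -> list[Variant]:
    letters = np.array(list("ACGT"))
    variants = []
    for j in range(n_snps):
        a, b = rng.choice(4, size=2, replace=False)
        variants.append(Variant(
            id=f"snp{j + 1:05d}", chromosome="1", position_bp=1 + j,
            allele_minor=str(letters[a]), allele_major=str(letters[b]),
        ))
    return variants


def _draw_haplotypes(
    n_hap: int, freqs: np.ndarray, ld_rho: float, rng: np.random.Generator
) -> np.ndarray:
    """Binary haplotypes with per-site allele frequency and adjacent
    correlation ~ld_rho via a first-order Markov chain."""
    m = freqs.shape[-1]
    hap = np.empty((n_hap, m), dtype=np.int8)
    f = np.broadcast_to(freqs, (n_hap, m))
    hap[:, 0] = rng.random(n_hap) < f[:, 0]
    for j in range(1, m):
        q_prev, q_cur = f[:, j - 1], f[:, j]
        sd = np.sqrt(q_cur * (1 - q_cur) / (q_prev * (1 - q_prev)))
        p1 = np.clip(q_cur + ld_rho * sd * (hap[:, j - 1] - q_prev), 0.0, 1.0)
        hap[:, j] = rng.random(n_hap) < p1
    return hap


def _genotype_batch(
    n: int, cfg: SimulationConfig, freqs: np.ndarray,
    subpop_freqs: np.ndarray | None, rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Draw n genotype rows (+ subpopulation labels)."""
    if subpop_freqs is None:
        f = freqs
        labels = np.zeros(n, dtype=int)
    else:
        _, mix = cfg.stratification  # type: ignore[misc]
        labels = (rng.random(n) < mix).astype(int)
        f = subpop_freqs[labels]
    geno = (_draw_haplotypes(n, f, cfg.ld_rho, rng)
            + _draw_haplotypes(n, f, cfg.ld_rho, rng)).astype(np.int8)
    if cfg.hwe_violation is not None:
        j, fin = cfg.hwe_violation
        q = freqs[j] if subpop_freqs is None else np.asarray(f)[..., j]
        p = 1 - q
        probs = np.stack(np.broadcast_arrays(
            p * p + fin * p * q, 2 * p * q * (1 - fin), q * q + fin * p * q), axis=-1)
        u = rng.random(n)
        cum = np.cumsum(probs, axis=-1)
        geno[:, j] = (u[:, None] > cum[..., :2].reshape(n, 2)).sum(axis=1)
    return geno, labels


def _disease_prob(geno: np.ndarray, cfg: SimulationConfig) -> np.ndarray:
    eta = np.full(geno.shape[0], np.log(cfg.baseline_risk / (1 - cfg.baseline_risk))
                  if 0 < cfg.baseline_risk < 1 else -np.inf)
    for j, orr in cfg.causal_effects:
        eta = eta + np.log(orr) * geno[:, j]
    return 1.0 / (1.0 + np.exp(-eta))


def _spectrum(cfg: SimulationConfig, rng: np.random.Generator):
    lo, hi = cfg.maf_range
    freqs = rng.uniform(lo, hi, size=cfg.n_snps)
    subpop_freqs = None
    if cfg.stratification is not None:
        F, _mix = cfg.stratification
        if F > 0:
            a = freqs * (1 - F) / F
            b = (1 - freqs) * (1 - F) / F
            subpop_freqs = np.clip(rng.beta(a, b, size=(2, cfg.n_snps)), 1e-4, 1 - 1e-4)
        else:
            subpop_freqs = np.stack([freqs, freqs])
    return freqs, subpop_freqs


def simulate_population(cfg: SimulationConfig, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Draw ``n`` population genotype rows and their disease indicators."""
    rng = np.random.default_rng(cfg.seed)
    freqs, subpop_freqs = _spectrum(cfg, rng)
    geno, _ = _genotype_batch(n, cfg, freqs, subpop_freqs, rng)
    disease = rng.random(n) < _disease_prob(geno, cfg)
    return geno, disease


def simulate_case_control(cfg: SimulationConfig) -> GenotypeDataset:
    """Rejection-sample genotypes to case/control quotas.

    Haplotypes follow a stationary first-order Markov chain (HWE by
    construction when stratification is off); disease follows
    ``logit(P) = logit(baseline_risk) + sum ln(OR) * dosage``.  The
    returned covariates include infant ``sex`` (1/2) and the true
    ``subpop`` label when stratification is on.
    """
    if cfg.baseline_risk <= 0 and cfg.n_cases > 0:
        raise ValueError("cannot sample cases with baseline_risk = 0")
    rng = np.random.default_rng(cfg.seed)
    freqs, subpop_freqs = _spectrum(cfg, rng)

    need_case, need_control = cfg.n_cases, cfg.n_controls
    cases, controls = [], []
    case_lab, control_lab = [], []
    batch = max(4 * (need_case + need_control), 2000)
    max_batches = 2000
    for _ in range(max_batches):
        if len(cases) >= need_case and len(controls) >= need_control:
            break
        geno, labels = _genotype_batch(batch, cfg, freqs, subpop_freqs, rng)
        affected = rng.random(batch) < _disease_prob(geno, cfg)
        if len(cases) < need_case:
            take = geno[affected][: need_case - len(cases)]
            cases.extend(take)
            case_lab.extend(labels[affected][: take.shape[0]])
        if len(controls) < need_control:
            take = geno[~affected][: need_control - len(controls)]
            controls.extend(take)
            control_lab.extend(labels[~affected][: take.shape[0]])
    else:
        raise RuntimeError("case/control quota not reached; disease model too extreme")

    dosage = np.array(cases + controls, dtype=float)
    phenotype = np.array([1] * need_case + [0] * need_control)
    n = dosage.shape[0]
    if cfg.missing_rate > 0:
        miss = rng.random(dosage.shape) < cfg.missing_rate
        dosage[miss] = np.nan
    sex = rng.integers(1, 3, size=n)
    cov = pd.DataFrame({"sex": sex.astype(float)})
    if cfg.stratification is not None:
        cov["subpop"] = np.array(case_lab + control_lab, dtype=float)
    samples = [f"case{i + 1:04d}" for i in range(need_case)] + \
              [f"ctrl{i + 1:04d}" for i in range(need_control)]
    variants = _make_variants(cfg.n_snps, rng)
    variants = [Variant(v.id, v.chromosome, 1 + j * cfg.position_spacing_bp,
                        v.allele_minor, v.allele_major)
                for j, v in enumerate(variants)]
    return GenotypeDataset(variants, samples, dosage, phenotype, cov)


# ---------------------------------------------------------------------------
# Dyads

def _dyad_multipliers(m, c, maternal_het_risk, params: DyadModelParams):
    S = np.array([1.0, params.S1, params.S2])
    R = np.array([1.0, params.R1, params.R2])
    mu = S[m] * R[c]
    mu = mu * np.where((c == 1) & maternal_het_risk, params.Im, 1.0)
    mu = mu * np.where((m == 0) & (c == 1), params.gamma01, 1.0)
    mu = mu * np.where((m == 2) & (c == 1), params.gamma21, 1.0)
    return mu


def simulate_dyads(cfg: SimulationConfig) -> tuple[DyadDataset, pd.DataFrame]:
    """Sample case and control mother-child dyads per variant.

    Mother genotype ~ HWE(q); the transmitted maternal allele is uniform
    over her two; the paternal allele is Bernoulli(q); the pregnancy is
    affected with probability ``baseline_risk * mu(m, c, origin)``.
    Case dyads are sampled conditional on affected, controls conditional
    on unaffected.  Returns the 7-cell count dataset plus a per-dyad
    truth log (variant, status, dosages, parental origin).
    """
    params = cfg.dyad_params
    q = params.q
    mu_max = max(params.multiplier(m, c, orig)
                 for (m, c) in DYAD_CELLS for orig in (False, True))
    if cfg.baseline_risk * mu_max > 1.0:
        raise ValueError("baseline_risk * max risk multiplier exceeds 1")
    if cfg.baseline_risk <= 0 and cfg.n_case_dyads > 0:
        raise ValueError("cannot sample case dyads with baseline_risk = 0")

    rng = np.random.default_rng(cfg.seed)
    n_var = cfg.n_dyad_snps if cfg.n_dyad_snps is not None else cfg.n_snps
    case_counts = np.zeros((n_var, 7), int)
    control_counts = np.zeros((n_var, 7), int)
    truth_rows = []
    batch = max(2000, int(4 * cfg.n_case_dyads / max(cfg.baseline_risk, 1e-6)))
    batch = min(batch, 2_000_000)
    cell_code = np.full((3, 3), -1, dtype=int)
    for k, (mm, cc) in enumerate(DYAD_CELLS):
        cell_code[mm, cc] = k
    for j in range(n_var):
        got_case = got_control = 0
        guard = 0
        while got_case < cfg.n_case_dyads or got_control < cfg.n_control_dyads:
            guard += 1
            if guard > 500:
                raise RuntimeError("dyad quota not reached")
            m = rng.binomial(2, q, size=batch)  # HWE genotype = 2 Bernoulli alleles
            transmit_risk = np.where(m == 2, True,
                                     np.where(m == 0, False, rng.random(batch) < 0.5))
            pat = rng.random(batch) < q
            c = transmit_risk.astype(int) + pat.astype(int)
            maternal_het_risk = transmit_risk & (c == 1)
            mu = _dyad_multipliers(m, c, maternal_het_risk, params)
            affected = rng.random(batch) < cfg.baseline_risk * mu
            for status, mask in ((1, affected), (0, ~affected)):
                need = cfg.n_case_dyads - got_case if status else cfg.n_control_dyads - got_control
                take = np.flatnonzero(mask)[:need]
                tgt = case_counts if status else control_counts
                tgt[j] += np.bincount(cell_code[m[take], c[take]], minlength=7)
                truth_rows.append(pd.DataFrame({
                    "variant_index": j, "case": status,
                    "mother_dosage": m[take], "child_dosage": c[take],
                    "maternal_risk_allele": transmit_risk[take],
                }))
                if status:
                    got_case += take.size
                else:
                    got_control += take.size

    variants = _make_variants(n_var, rng)
    dyads = DyadDataset(variants, case_counts, control_counts,
                        cfg.n_case_dyads, cfg.n_control_dyads)
    truth = (pd.concat(truth_rows, ignore_index=True) if truth_rows
             else pd.DataFrame(columns=["variant_index", "case", "mother_dosage",
                                        "child_dosage", "maternal_risk_allele"]))
    return dyads, truth


def inject_missingness(
    dataset: GenotypeDataset,
    per_sample_rates: Mapping[str, float] | None = None,
    per_snp_rates: Mapping[str, float] | None = None,
    seed: int = 0,
) -> GenotypeDataset:
    """Set entries missing independently at combined per-sample/per-SNP rates."""
    rng = np.random.default_rng(seed)
    srates = np.zeros(dataset.n_samples)
    vrates = np.zeros(dataset.n_variants)
    if per_sample_rates:
        for i, s in enumerate(dataset.samples):
            srates[i] = per_sample_rates.get(s, 0.0)
    if per_snp_rates:
        for j, v in enumerate(dataset.variants):
            vrates[j] = per_snp_rates.get(v.id, 0.0)
    if ((srates < 0) | (srates > 1)).any() or ((vrates < 0) | (vrates > 1)).any():
        raise ValueError("rates must lie in [0, 1]")
    rate = 1.0 - np.outer(1.0 - srates, 1.0 - vrates)
    miss = rng.random(dataset.dosage.shape) < rate
    dosage = dataset.dosage.copy()
    dosage[miss] = np.nan
    return GenotypeDataset(list(dataset.variants), list(dataset.samples),
                           dosage, dataset.phenotype.copy(),
                           dataset.covariates.copy())
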