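"""Cross-validated weighted genetic risk score with quartile odds ratios.

Ten causal SNPs (OR 1.8 each) in a 500/500 cohort: each replicate of
the 10-fold cross-validation trains per-SNP weights on 9 folds, scores
the held-out fold, cuts the pooled scores at the control quartiles, and
fits quartile ORs adjusted for infant sex.  Replicates average out the
partition noise.
"""

from dyadgwas import (SimulationConfig, crossval_wgrs, mode_impute,
                      simulate_case_control)

cfg = SimulationConfig(n_cases=500, n_controls=500, n_snps=10,
                       maf_range=(0.3, 0.3),
                       causal_effects=[(j, 1.8) for j in range(10)], seed=5)
dataset = mode_impute(simulate_case_control(cfg))
snp_set = [v.id for v in dataset.variants]

summary = crossval_wgrs(dataset, snp_set, covariates=("sex",),
                        folds=10, repeats=50, seed=3)
print(summary.to_frame().to_string(index=False))
print(f"AUC {summary.auc:.3f} (95% CI {summary.auc_ci[0]:.3f}-{summary.auc_ci[1]:.3f})")
print(f"median 3-df global p across replicates: {summary.global_p_median:.2e}")
# Rising quartile ORs (Q4 >> Q2 > 1) and AUC well above 0.5 show the
# score separates cases from controls without in-sample overfitting.
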