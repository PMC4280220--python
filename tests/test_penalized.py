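"""Penalized selection: LD, the coordinate-descent engine against
closed-form and sklearn oracles, path structure, and the joint refit."""

import numpy as np
import pytest

from dyadgwas import (
    PenalizedConfig,
    SimulationConfig,
    association_scan,
    cmcp_bilevel_select,
    lasso_select_cv,
    ld_expand,
    mode_impute,
    pairwise_r2,
    refit_joint,
    simulate_case_control,
)
from dyadgwas.geno_io import GenotypeDataset, Variant
from dyadgwas.penalized import _cd_sweeps, lambda_max, mcp_select_cv


class TestPairwiseR2:
    def test_identical_vectors(self):
        v = np.array([0, 1, 2, 1, 0], float)
        assert pairwise_r2(v, v) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(3)
        a = rng.binomial(2, 0.3, 10_000).astype(float)
        b = rng.binomial(2, 0.3, 10_000).astype(float)
        assert pairwise_r2(a, b) < 0.01

    def test_pairwise_complete_convention(self):
        a = np.array([0, 1, 2, np.nan, 1], float)
        b = np.array([0, 1, 2, 1, np.nan], float)
        assert pairwise_r2(a, b) == pytest.approx(1.0)

    def test_zero_variance_flagged(self):
        assert np.isnan(pairwise_r2(np.ones(5), np.array([0, 1, 2, 1, 0.0])))

    def test_decay_with_distance_in_ld_chain(self):
        from dyadgwas import simulate_population
        cfg = SimulationConfig(n_snps=30, maf_range=(0.3, 0.4), ld_rho=0.8, seed=7)
        geno, _ = simulate_population(cfg, 5000)
        g = geno.astype(float)
        lag1 = np.mean([pairwise_r2(g[:, j], g[:, j + 1]) for j in range(25)])
        lag5 = np.mean([pairwise_r2(g[:, j], g[:, j + 5]) for j in range(25)])
        assert lag1 > lag5


def _complete_dataset(seed=11, n=400, m=60, causal=(), maf=(0.2, 0.4)):
    cfg = SimulationConfig(n_cases=n // 2, n_controls=n // 2, n_snps=m,
                           maf_range=maf, causal_effects=list(causal), seed=seed)
    return mode_impute(simulate_case_control(cfg))


class TestCdEngineOracles:
    def test_orthonormal_soft_threshold(self):
        """On an orthonormal design the lasso CD solution is exactly the
        soft-thresholded univariate estimate (linear-model limit)."""
        rng = np.random.default_rng(13)
        n, p = 200, 8
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)  # columns: x'x/n = 1, orthogonal
        z = rng.normal(size=n) * 2
        lam = 0.15
        beta = np.zeros(p)
        alpha = np.zeros(0)
        res = z.copy()
        _cd_sweeps(np.asfortranarray(X), np.empty((n, 0)), res, beta, alpha,
                   np.full(p, lam), np.ones(p), 1.0, 1e-12, 500)
        uni = X.T @ z / n
        expected = np.sign(uni) * np.maximum(np.abs(uni) - lam, 0)
        np.testing.assert_allclose(beta, expected, atol=1e-10)

    def test_empty_selection_at_lambda_max(self):
        """KKT: any penalty at or above max |x'(y-ybar)|/n selects nothing."""
        ds = _complete_dataset(seed=17, causal=[(0, 2.0)])
        lmax = lambda_max(ds.dosage, ds.phenotype.astype(float))
        cfg = PenalizedConfig(cv_folds=2, penalty_grid=np.array([lmax * 1.001]), seed=1)
        sel = lasso_select_cv(ds, config=cfg)
        assert sel.selected == []

    def test_matches_sklearn_l1_logistic(self):
        """Independent oracle: sklearn's saga L1 path on the same design."""
        from sklearn.linear_model import LogisticRegression
        ds = _complete_dataset(seed=19, n=300, m=25, causal=[(0, 2.0), (5, 0.5)])
        X = ds.dosage
        Xs = (X - X.mean(0)) / X.std(0)
        y = ds.phenotype.astype(float)
        lam = 0.03
        cfg = PenalizedConfig(cv_folds=2, penalty_grid=np.array([lam]), seed=1)
        sel = lasso_select_cv(ds, config=cfg)
        mine = np.zeros(X.shape[1])
        for v, coef in sel.selected:
            j = ds.variant_index(v.id)
            mine[j] = coef * X[:, j].std()  # back to standardized scale
        ref = LogisticRegression(l1_ratio=1.0, C=1.0 / (X.shape[0] * lam),
                                 solver="saga", max_iter=20000, tol=1e-10,
                                 fit_intercept=True)
        ref.fit(Xs, y)
        np.testing.assert_allclose(mine, ref.coef_[0], atol=5e-3)

    def test_path_support_nonincreasing_in_penalty(self):
        ds = _complete_dataset(seed=23, causal=[(0, 2.0), (1, 1.8)])
        cfg = PenalizedConfig(cv_folds=3, n_lambda=25, seed=2)
        sel = lasso_select_cv(ds, config=cfg)
        # re-solve the full path and count supports
        from dyadgwas.penalized import _PenalizedLogistic
        y = ds.phenotype.astype(float)
        solver = _PenalizedLogistic(ds.dosage, y, np.ones((ds.n_samples, 1)),
                                    "lasso", 3.0, None, 10_000, 1e-6)
        lambdas = solver.lambda_grid(25, 0.01)
        betas, _, _ = solver.fit_path(lambdas)
        sizes = (betas != 0).sum(axis=1)
        assert (np.diff(sizes) >= 0).all()  # descending grid -> growing support

    def test_cv_folds_deterministic_in_seed(self):
        ds = _complete_dataset(seed=29, causal=[(0, 2.0)])
        cfg = PenalizedConfig(cv_folds=4, n_lambda=12, seed=5)
        a = lasso_select_cv(ds, config=cfg)
        b = lasso_select_cv(ds, config=cfg)
        assert a.chosen_penalty == b.chosen_penalty
        np.testing.assert_array_equal(a.cv_curve["mean_deviance"],
                                      b.cv_curve["mean_deviance"])


class TestCmcp:
    def test_singleton_groups_reduce_to_plain_mcp(self):
        ds = _complete_dataset(seed=31, n=300, m=30, causal=[(0, 2.2), (7, 1.8)])
        groups = {v.id: v.id for v in ds.variants}  # every SNP its own gene
        grid = None
        cfg_m = PenalizedConfig(method="cmcp", cv_folds=3, n_lambda=15, seed=3)
        mcp = mcp_select_cv(ds, config=cfg_m)
        cfg_c = PenalizedConfig(method="cmcp", cv_folds=3, n_lambda=15, seed=3,
                                groups=groups)
        cmcp = cmcp_bilevel_select(ds, config=cfg_c)
        assert set(mcp.selected_ids) == set(cmcp.selected_ids)
        assert mcp.chosen_penalty == cmcp.chosen_penalty

    def test_empty_above_path_maximum(self):
        ds = _complete_dataset(seed=37, m=20, causal=[(0, 2.0)])
        groups = {v.id: f"g{j // 4}" for j, v in enumerate(ds.variants)}
        lmax = lambda_max(ds.dosage, ds.phenotype.astype(float))
        cfg = PenalizedConfig(method="cmcp", cv_folds=2, groups=groups,
                              penalty_grid=np.array([lmax * 1.01]), seed=1)
        sel = cmcp_bilevel_select(ds, config=cfg)
        assert sel.selected == []

    def test_missing_group_errors(self):
        ds = _complete_dataset(seed=41, m=6)
        cfg = PenalizedConfig(method="cmcp", cv_folds=2,
                              groups={ds.variants[0].id: "g"}, seed=1)
        with pytest.raises(ValueError, match="gene group"):
            cmcp_bilevel_select(ds, config=cfg)


class TestLdExpand:
    def _with_duplicate(self):
        ds = _complete_dataset(seed=43, m=10, causal=[(0, 2.5)])
        variants = list(ds.variants) + [Variant("dup", "1",
                                                ds.variants[0].position_bp + 1,
                                                "A", "G")]
        dosage = np.column_stack([ds.dosage, ds.dosage[:, 0]])
        return GenotypeDataset(variants, ds.samples, dosage, ds.phenotype,
                               ds.covariates)

    def test_duplicate_column_found_with_r2_one(self):
        ds = self._with_duplicate()
        cfg = PenalizedConfig(cv_folds=2, n_lambda=10, seed=1)
        sel = lasso_select_cv(ds, config=cfg)
        if not any(v.id == ds.variants[0].id for v, _ in sel.selected):
            pytest.skip("first SNP not selected in this draw")
        out = ld_expand(sel, ds)
        proxies = {(a, b): r for a, b, r in out.ld_expanded}
        assert proxies.get((ds.variants[0].id, "dup")) == pytest.approx(1.0)

    def test_no_proxy_outside_window(self):
        ds = _complete_dataset(seed=47, m=5)
        # positions are 5 kb apart and independent SNPs: nothing at r2 >= 0.8
        cfg = PenalizedConfig(cv_folds=2, n_lambda=10, seed=2)
        sel = lasso_select_cv(ds, config=cfg)
        if not sel.selected:
            pytest.skip("empty selection in this draw")
        out = ld_expand(sel, ds, r2_threshold=0.8, window_bp=1)
        assert out.ld_expanded == []

    def test_expansion_grows_with_ld(self):
        sizes = {}
        for rho in (0.0, 0.97):
            cfg = SimulationConfig(n_cases=250, n_controls=250, n_snps=40,
                                   maf_range=(0.3, 0.4), ld_rho=rho,
                                   causal_effects=[(20, 2.5)], seed=53)
            ds = mode_impute(simulate_case_control(cfg))
            pcfg = PenalizedConfig(cv_folds=3, n_lambda=15, seed=3)
            sel = lasso_select_cv(ds, config=pcfg)
            if not sel.selected:
                pytest.skip("empty selection in this draw")
            sizes[rho] = len(ld_expand(sel, ds).ld_expanded)
        assert sizes[0.97] > sizes[0.0]

    def test_empty_selection_rejected(self):
        ds = _complete_dataset(seed=59, m=5)
        from dyadgwas import PenalizedSelection
        import pandas as pd
        empty = PenalizedSelection([], 1.0, pd.DataFrame())
        with pytest.raises(ValueError, match="empty"):
            ld_expand(empty, ds)


class TestRefitJoint:
    def test_single_snp_matches_scan(self):
        ds = _complete_dataset(seed=61, m=10, causal=[(2, 2.0)])
        records, _ = association_scan(ds)
        marginal = next(r for r in records if r.variant.id == ds.variants[2].id)
        joint = refit_joint(ds, [ds.variants[2].id])
        assert joint[0].odds_ratio == pytest.approx(marginal.odds_ratio, rel=1e-8)
        assert joint[0].p_value == pytest.approx(marginal.p_value, rel=1e-6)

    def test_independent_snps_keep_marginal_effects(self):
        ds = _complete_dataset(seed=67, n=5000, m=10,
                               causal=[(0, 2.0), (5, 2.0)], maf=(0.3, 0.3))
        records, _ = association_scan(ds)
        marg = {r.variant.id: np.log(r.odds_ratio) for r in records}
        joint = refit_joint(ds, [ds.variants[0].id, ds.variants[5].id])
        for rec in joint:
            assert abs(np.log(rec.odds_ratio) - marg[rec.variant.id]) < 0.1

    def test_collinear_pair_flagged(self):
        ds = _complete_dataset(seed=71, m=6)
        variants = list(ds.variants) + [Variant("dup", "1", 999, "A", "G")]
        dosage = np.column_stack([ds.dosage, ds.dosage[:, 0]])
        ds2 = GenotypeDataset(variants, ds.samples, dosage, ds.phenotype,
                              ds.covariates)
        out = refit_joint(ds2, [ds2.variants[0].id, "dup"])
        assert all(r.flag == "collinear-ridge" for r in out)
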