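"""Dyad multinomial likelihood: cell probabilities against an exhaustive
transmission-enumeration oracle, MLE behavior, LRTs, and BIC selection."""

import numpy as np
import pytest
from scipy import stats

from dyadgwas import (
    DYAD_CELLS,
    DyadModelFit,
    DyadModelParams,
    SimulationConfig,
    dyad_cell_probabilities,
    dyad_loglik,
    fit_dyad_model,
    imprinting_scan,
    likelihood_ratio_test,
    sample_dyad_counts,
    select_best_model,
    simulate_dyads,
)


def enumeration_oracle(params: DyadModelParams) -> np.ndarray:
    """Case cell probabilities by brute force over (mother genotype,
    maternal transmitted allele, paternal allele)."""
    q = params.q
    acc = dict.fromkeys(DYAD_CELLS, 0.0)
    for m, pm in ((0, (1 - q) ** 2), (1, 2 * q * (1 - q)), (2, q * q)):
        for mt in (0, 1):
            if (m == 0 and mt == 1) or (m == 2 and mt == 0):
                continue
            pt = 0.5 if m == 1 else 1.0
            for pa, pp in ((0, 1 - q), (1, q)):
                c = mt + pa
                acc[(m, c)] += pm * pt * pp * params.multiplier(m, c, bool(mt))
    vec = np.array([acc[cell] for cell in DYAD_CELLS])
    return vec / vec.sum()


def random_params(rng) -> DyadModelParams:
    return DyadModelParams(
        q=rng.uniform(0.05, 0.95),
        R1=rng.lognormal(0, 0.5), R2=rng.lognormal(0, 0.5),
        S1=rng.lognormal(0, 0.5), S2=rng.lognormal(0, 0.5),
        Im=rng.lognormal(0, 0.5),
        gamma01=rng.lognormal(0, 0.5), gamma21=rng.lognormal(0, 0.5),
    )


class TestCellProbabilities:
    def test_null_model_collapses_to_population(self):
        case, control = dyad_cell_probabilities(DyadModelParams(q=0.5))
        np.testing.assert_allclose(case, control, atol=1e-15)
        assert case[0] == pytest.approx(0.125)

    def test_imprinting_acts_only_on_maternal_origin_hets(self):
        """(2,1) is always maternally derived, (0,1) never: Im raises the
        case/control ratio of (2,1) relative to (0,1)."""
        case, control = dyad_cell_probabilities(DyadModelParams(q=0.5, Im=2.0))
        k21 = DYAD_CELLS.index((2, 1))
        k01 = DYAD_CELLS.index((0, 1))
        assert case[k21] / control[k21] > case[k01] / control[k01]

    def test_matches_enumeration_oracle(self):
        rng = np.random.default_rng(61)
        for _ in range(300):
            params = random_params(rng)
            case, control = dyad_cell_probabilities(params)
            np.testing.assert_allclose(case, enumeration_oracle(params), atol=1e-12)
            assert case.sum() == pytest.approx(1.0, abs=1e-12)
            assert control.sum() == pytest.approx(1.0, abs=1e-12)

    def test_degenerate_frequency_rejected(self):
        with pytest.raises(ValueError):
            DyadModelParams(q=0.0)


class TestDyadLoglik:
    def test_single_dyad_null(self):
        counts = np.zeros(7)
        counts[0] = 1
        ll = dyad_loglik(counts, np.zeros(7), DyadModelParams(q=0.5))
        assert ll == pytest.approx(np.log(0.125))

    def test_linear_in_counts(self):
        rng = np.random.default_rng(67)
        params = random_params(rng)
        case = rng.integers(0, 20, 7).astype(float)
        ctrl = rng.integers(0, 20, 7).astype(float)
        assert dyad_loglik(2 * case, 2 * ctrl, params) == pytest.approx(
            2 * dyad_loglik(case, ctrl, params))

    def test_truth_maximizes_expected_loglik(self):
        """Counts proportional to the model's own cells: the generating
        parameters sit at a stationary point of the likelihood."""
        params = DyadModelParams(q=0.3, S1=1.5, R1=1.3)
        case, control = dyad_cell_probabilities(params)
        case_counts, ctrl_counts = 10_000 * case, 10_000 * control
        ll0 = dyad_loglik(case_counts, ctrl_counts, params)
        for dq in (-1e-4, 1e-4):
            perturbed = DyadModelParams(q=params.q + dq, S1=params.S1, R1=params.R1)
            assert dyad_loglik(case_counts, ctrl_counts, perturbed) <= ll0 + 1e-6


class TestFitDyadModel:
    def test_parameter_recovery_m_plus_f(self):
        """Truth q=.3, S=(1.5,2.2), R=(1.3,1.7); 5000+5000 dyads; all
        log-parameter errors within ±0.15."""
        truth = DyadModelParams(q=0.3, S1=1.5, S2=2.2, R1=1.3, R2=1.7)
        rng = np.random.default_rng(71)
        case, ctrl = sample_dyad_counts(truth, 5000, 5000, rng)
        fit = fit_dyad_model(case, ctrl, "M+F")
        for name in ("S1", "S2", "R1", "R2"):
            err = abs(np.log(getattr(fit.params, name)) - np.log(getattr(truth, name)))
            assert err < 0.15, name
        assert abs(np.log(fit.params.q) - np.log(truth.q)) < 0.15

    def test_null_truth_recovers_unit_multipliers(self):
        truth = DyadModelParams(q=0.4)
        rng = np.random.default_rng(73)
        case, ctrl = sample_dyad_counts(truth, 5000, 5000, rng)
        fit = fit_dyad_model(case, ctrl, "M+F")
        for name in ("S1", "S2", "R1", "R2"):
            assert abs(np.log(getattr(fit.params, name))) < 0.1, name

    def test_small_table_matches_grid_search(self):
        """q + one multiplier on <=30 dyads vs a dense 2-D grid refine."""
        case = np.array([2, 4, 3, 5, 1, 0, 0], float)
        ctrl = np.array([4, 3, 2, 4, 1, 1, 0], float)
        fit = fit_dyad_model(case, ctrl, ("S1",))
        best = -np.inf
        qs = np.linspace(0.05, 0.95, 181)
        ss = np.exp(np.linspace(-2, 2, 161))
        for q in qs:
            for s in ss:
                ll = dyad_loglik(case, ctrl, DyadModelParams(q=q, S1=s))
                best = max(best, ll)
        # refine around the coarse optimum
        q0, s0 = fit.params.q, fit.params.S1
        for q in np.linspace(max(q0 - 0.02, 0.01), min(q0 + 0.02, 0.99), 81):
            for s in np.exp(np.linspace(np.log(s0) - 0.05, np.log(s0) + 0.05, 81)):
                ll = dyad_loglik(case, ctrl, DyadModelParams(q=q, S1=s))
                best = max(best, ll)
        assert fit.loglik == pytest.approx(best, abs=1e-4)

    def test_bic_convention(self):
        rng = np.random.default_rng(79)
        case, ctrl = sample_dyad_counts(DyadModelParams(q=0.3), 100, 100, rng)
        fit = fit_dyad_model(case, ctrl, "M+F")
        assert fit.k == 5
        assert fit.bic == pytest.approx(-2 * fit.loglik + 5 * np.log(200))

    def test_guard_on_tiny_tables(self):
        with pytest.raises(ValueError, match="20"):
            fit_dyad_model(np.array([1, 0, 0, 0, 0, 0, 0]), np.zeros(7), "Null")

    def test_allele_relabel_invariance(self):
        """Swapping the risk-allele label mirrors every cell; the maximized
        loglik of symmetric models (Null, F) is unchanged."""
        rng = np.random.default_rng(83)
        case, ctrl = sample_dyad_counts(
            DyadModelParams(q=0.3, R1=1.5, R2=2.0), 800, 800, rng)
        mirror = {(m, c): (2 - m, 2 - c) for m, c in DYAD_CELLS}
        perm = [DYAD_CELLS.index(mirror[cell]) for cell in DYAD_CELLS]
        for model in ("Null", "F"):
            a = fit_dyad_model(case, ctrl, model)
            b = fit_dyad_model(case[perm], ctrl[perm], model)
            assert a.loglik == pytest.approx(b.loglik, abs=1e-5)


class TestLikelihoodRatioTest:
    @staticmethod
    def _fit(model, loglik, k):
        return DyadModelFit(model, DyadModelParams(q=0.3), loglik, k,
                            -2 * loglik + k * np.log(420), True)

    @pytest.mark.parametrize("ll_full,ll_red,df,published", [
        (-349.57, -356.546, 2, 13.9504),   # interaction vs maternal+fetal
        (-356.546, -373.757, 4, 34.423),   # maternal+fetal vs null
        (-368.019, -373.757, 2, 11.4755),  # fetal vs null
        (-366.111, -373.757, 2, 15.293),   # maternal vs null
        (-356.546, -368.019, 2, 22.9475),  # maternal+fetal vs fetal
    ])
    def test_published_statistics_recomputed(self, ll_full, ll_red, df, published):
        """LRTs recomputed from printed 3-decimal log-likelihoods match the
        printed statistics within rounding (<=0.2% relative)."""
        stat, p = likelihood_ratio_test(self._fit("A", ll_full, 5),
                                        self._fit("B", ll_red, 1), df)
        assert stat == pytest.approx(published, rel=2e-3)
        assert 0 < p < 1

    def test_identical_logliks(self):
        stat, p = likelihood_ratio_test(self._fit("A", -100.0, 5),
                                        self._fit("B", -100.0, 3), 2)
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_negative_statistic_errors(self):
        with pytest.raises(RuntimeError):
            likelihood_ratio_test(self._fit("A", -101.0, 5),
                                  self._fit("B", -100.0, 3), 2)


class TestSelectBestModel:
    def test_table_layout_fixed(self):
        rng = np.random.default_rng(89)
        case, ctrl = sample_dyad_counts(DyadModelParams(q=0.3), 200, 200, rng)
        table = select_best_model(case, ctrl)
        assert list(table.rows["comparison"]) == [
            "Model I vs Model M+F", "Model M+F vs Model F", "Model M+F vs Model M",
            "Model M+F vs Model Null", "Model M vs Model Null",
            "Model F vs Model Null", "Model Null",
        ]
        assert table.selected_model in ("Null", "F", "M", "M+F", "I")

    def test_interaction_truth_selected(self):
        truth = DyadModelParams(q=0.3, gamma01=2.5, gamma21=2.5)
        rng = np.random.default_rng(97)
        hits = 0
        for _ in range(10):
            case, ctrl = sample_dyad_counts(truth, 5000, 5000, rng)
            hits += select_best_model(case, ctrl).selected_model == "I"
        assert hits >= 8


class TestImprintingScan:
    def test_row_count_and_flags(self):
        cfg = SimulationConfig(n_case_dyads=300, n_control_dyads=300, n_snps=3,
                               dyad_params=DyadModelParams(q=0.3, Im=1.0),
                               baseline_risk=0.01, seed=101)
        dyads, _ = simulate_dyads(cfg)
        out = imprinting_scan(dyads)
        assert out.shape[0] == 3
        assert set(out.columns) >= {"variant", "p_value", "lrt", "significant"}

    def test_power_under_strong_imprinting(self):
        truth = DyadModelParams(q=0.3, Im=3.0)
        rng = np.random.default_rng(103)
        rejections = 0
        for _ in range(10):
            case, ctrl = sample_dyad_counts(truth, 2000, 2000, rng)
            fit_mf = fit_dyad_model(case, ctrl, "M+F")
            fit_im = fit_dyad_model(case, ctrl, "M+F+Im")
            _, p = likelihood_ratio_test(fit_im, fit_mf, 1)
            rejections += p < 0.05
        assert rejections >= 8
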