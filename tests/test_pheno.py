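import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cssmap.design import build_design_matrix
from cssmap.pheno import (
    analyze_trait,
    bootstrap_inference,
    fisher_combine,
    fit_combined_sex_model,
    fit_sex_model,
    heritable_share,
    ivw_combine,
    joint_test,
    winsorize,
)
from cssmap.simulate import PhenoSimConfig, simulate_phenotypes


class TestWinsorize:
    def test_hand_example(self):
        # median 2.5, raw MAD 1.0 -> ceiling 6.5
        res = winsorize([1, 2, 3, 100], k=4)
        assert res.ceiling == pytest.approx(6.5)
        assert list(res.values) == [1, 2, 3, 6.5]
        assert res.n_modified == 1
        assert res.ceiling_scaled == pytest.approx(2.5 + 4 * 1.4826 * 1.0)

    def test_identical_values_warn(self):
        with pytest.warns(UserWarning, match="MAD"):
            res = winsorize([5.0, 5.0, 5.0, 5.0])
        assert res.n_modified == 0

    def test_idempotent_and_order_preserving(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 10, 200)
        x[:5] += 200
        first = winsorize(x, 4)
        second = winsorize(first.values, 4)
        np.testing.assert_array_equal(first.values, second.values)
        below = x <= first.ceiling
        np.testing.assert_array_equal(first.values[below], x[below])
        assert first.values.max() <= first.ceiling

    def test_no_floor_applied(self):
        res = winsorize([-100, 1, 2, 3], 4)
        assert res.values[0] == -100


class TestCombination:
    def test_fisher_examples(self):
        assert fisher_combine([1.0, 1.0]) == pytest.approx(1.0)
        # chi-square df 4 survival at -2 ln(0.25) = 2.7726
        assert fisher_combine([0.5, 0.5]) == pytest.approx(0.5966, abs=1e-4)

    def test_fisher_monotone(self):
        base = fisher_combine([0.3, 0.2])
        assert fisher_combine([0.2, 0.2]) < base
        assert fisher_combine([0.3, 0.1]) < base

    def test_fisher_rejects_zero(self):
        with pytest.raises(ValueError):
            fisher_combine([0.0, 0.5])

    def test_ivw_hand_example(self):
        beta, var, w = ivw_combine(1.0, 1.0, 3.0, 0.5)
        assert beta == pytest.approx(2.3333, abs=1e-4)
        assert var == pytest.approx(0.3333, abs=1e-4)
        assert w == pytest.approx(0.3333, abs=1e-4)

    def test_ivw_symmetry_and_limits(self):
        beta, var, w = ivw_combine(2.0, 1.0, 4.0, 1.0)
        assert beta == pytest.approx(3.0) and w == pytest.approx(0.5)
        beta, var, _ = ivw_combine(2.0, 1e-10, 4.0, 1.0)
        assert beta == pytest.approx(2.0, abs=1e-6)

    def test_ivw_variance_dominates_and_estimate_between(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            bf, bm = rng.normal(size=2)
            vf, vm = rng.uniform(0.1, 2, 2)
            beta, var, w = ivw_combine(bf, vf, bm, vm)
            assert var <= min(vf, vm) + 1e-12
            assert min(bf, bm) - 1e-12 <= beta <= max(bf, bm) + 1e-12
            assert 0 <= w <= 1

    def test_ivw_rejects_nonpositive_variance(self):
        with pytest.raises(ValueError):
            ivw_combine(1.0, 0.0, 2.0, 1.0)


class TestSexFits:
    def test_noise_free_recovery(self):
        cfg = PhenoSimConfig(
            maternal_panel=("3",), paternal_panel=("4",), exclusions=(),
            cell_sizes=(6, 6, 6),
            main_effects={"glucose_mg_dl": {"M": {"3": 10.0, "4": -5.0},
                                            "F": {"3": 10.0, "4": -5.0}}},
            interaction_effects={"glucose_mg_dl": {
                "M": {("3", "4"): 7.0}, "F": {("3", "4"): 7.0}}},
            residual_sd={"F": {"body_weight_g": 1e-9, "glucose_mg_dl": 1e-9},
                         "M": {"body_weight_g": 1e-9, "glucose_mg_dl": 1e-9}},
            outlier_rate=0.0, seed=0,
        )
        table, _ = simulate_phenotypes(cfg)
        fit = fit_sex_model(table, "M", "glucose_mg_dl")
        assert fit.params["mat3"] == pytest.approx(10.0, abs=1e-6)
        assert fit.params["pat4"] == pytest.approx(-5.0, abs=1e-6)
        assert fit.params["int3:4"] == pytest.approx(7.0, abs=1e-6)

    def test_adjusted_r2_identity(self, tiny_pheno):
        table, _, _ = tiny_pheno
        fit = fit_sex_model(table, "F", "glucose_mg_dl")
        # independent residual-SS computation
        X = fit.design.X.to_numpy()
        y = fit.y
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        rss = np.sum((y - X @ beta) ** 2)
        tss = np.sum((y - y.mean()) ** 2)
        r2 = 1 - rss / tss
        n, p = X.shape
        assert fit.r2 == pytest.approx(r2)
        assert fit.r2_adj == pytest.approx(1 - (1 - r2) * (n - 1) / (n - p))
        assert fit.r2_adj <= fit.r2

    def test_additive_model_matches_full_without_interactions(self):
        # interaction-free truth: both models estimate the same main effects
        cfg = PhenoSimConfig(
            maternal_panel=("3",), paternal_panel=("4",), exclusions=(),
            cell_sizes=(5000, 5000, 5000),
            main_effects={"glucose_mg_dl": {"M": {"3": 12.0}, "F": {"3": 12.0}}},
            outlier_rate=0.0, seed=4,
        )
        table, _ = simulate_phenotypes(cfg)
        full = fit_sex_model(table, "M", "glucose_mg_dl", True)
        add = fit_sex_model(table, "M", "glucose_mg_dl", False)
        assert full.params["mat3"] == pytest.approx(add.params["mat3"], abs=1.0)
        assert add.params["mat3"] == pytest.approx(12.0, abs=1.0)

    def test_too_few_observations(self):
        cfg = PhenoSimConfig(maternal_panel=("3", "6"), paternal_panel=("4", "5"),
                             exclusions=(), cell_sizes=(1, 1, 1), seed=0)
        table, _ = simulate_phenotypes(cfg)
        with pytest.raises(ValueError, match="observations|rank"):
            fit_sex_model(table, "M", "glucose_mg_dl", min_cell=None)


class TestJointTest:
    def test_single_term_equals_squared_t(self, tiny_pheno):
        table, _, _ = tiny_pheno
        fit = fit_sex_model(table, "M", "glucose_mg_dl")
        # restrict to a one-term class by direct quadratic form
        term = "mat3"
        t_stat = fit.params[term] / fit.bse[term]
        beta = np.array([fit.params[term]])
        V = np.array([[fit.cov.loc[term, term]]])
        F = float(beta @ np.linalg.solve(V, beta))
        assert F == pytest.approx(t_stat**2)

    def test_matches_nested_rss_oracle(self, tiny_pheno):
        table, _, _ = tiny_pheno
        for klass in ("main", "interaction"):
            fit = fit_sex_model(table, "F", "glucose_mg_dl")
            F, df1, df2, p = joint_test(fit, klass)
            X = fit.design.X
            y = fit.y
            keep = [c for c in X.columns
                    if c not in fit.design.terms_of_class(klass)]
            b1, *_ = np.linalg.lstsq(X.to_numpy(), y, rcond=None)
            b0, *_ = np.linalg.lstsq(X[keep].to_numpy(), y, rcond=None)
            rss1 = np.sum((y - X.to_numpy() @ b1) ** 2)
            rss0 = np.sum((y - X[keep].to_numpy() @ b0) ** 2)
            F_oracle = ((rss0 - rss1) / df1) / (rss1 / df2)
            assert F == pytest.approx(F_oracle, rel=1e-8)
            assert p == pytest.approx(stats.f.sf(F_oracle, df1, df2), rel=1e-8)

    def test_null_calibration(self):
        # all-null design: classical F p-values are Uniform(0,1)
        rng = np.random.default_rng(8)
        pvals = []
        base = PhenoSimConfig(maternal_panel=("3",), paternal_panel=("4",),
                              exclusions=(), cell_sizes=(25, 25, 25),
                              outlier_rate=0.0, seed=0)
        table, _ = simulate_phenotypes(base)
        males = table[table.sex == "M"].reset_index(drop=True)
        dm = build_design_matrix(males)
        X = dm.X
        for _ in range(2000):
            males = males.copy()
            males["glucose_mg_dl"] = rng.normal(100, 10, len(males))
            fit = fit_sex_model(males, "M", "glucose_mg_dl", min_cell=None)
            pvals.append(joint_test(fit, "interaction")[3])
        assert stats.kstest(pvals, "uniform").pvalue > 0.01

    def test_empty_term_class_rejected(self, tiny_pheno):
        table, _, _ = tiny_pheno
        fit = fit_sex_model(table, "M", "glucose_mg_dl", with_interactions=False)
        with pytest.raises(ValueError, match="no terms"):
            joint_test(fit, "interaction")


class TestCombinedSexModel:
    def test_recovers_sex_offset(self):
        cfg = PhenoSimConfig(maternal_panel=("3",), paternal_panel=("4",),
                             exclusions=(), cell_sizes=(200, 200, 200),
                             outlier_rate=0.0, seed=2)
        table, _ = simulate_phenotypes(cfg)
        fit = fit_combined_sex_model(table, "glucose_mg_dl")
        true_offset = (cfg.baselines["M"]["glucose_mg_dl"]
                       - cfg.baselines["F"]["glucose_mg_dl"])
        assert fit.params["sexM"] == pytest.approx(true_offset, abs=2.0)

    def test_single_sex_rejected(self, tiny_pheno):
        table, _, _ = tiny_pheno
        with pytest.raises(ValueError, match="both sexes"):
            fit_combined_sex_model(table[table.sex == "M"], "glucose_mg_dl")


class TestBootstrap:
    @pytest.fixture(scope="class")
    def boot(self, tiny_pheno):
        table, _, _ = tiny_pheno
        return bootstrap_inference(table, "glucose_mg_dl", B=600, seed=5)

    def test_adjusted_p_dominates_raw(self, boot):
        for e in boot.effects:
            assert e.adj_p >= e.raw_p - 1e-12

    def test_reproducible_under_seed(self, tiny_pheno, boot):
        table, _, _ = tiny_pheno
        again = bootstrap_inference(table, "glucose_mg_dl", B=600, seed=5)
        pd.testing.assert_frame_equal(boot.effects_frame(),
                                      again.effects_frame())

    def test_planted_interaction_detected(self, tiny_pheno, boot):
        table, truth, _ = tiny_pheno
        eff = {e.term: e for e in boot.effects}
        assert eff["int6:5"].adj_p < 0.05
        # estimate near the IVW-weighted truth (-18 F / -15.6 M)
        assert -45 < eff["int6:5"].estimate < -20

    def test_ci_brackets_estimate(self, boot):
        for e in boot.effects:
            assert e.ci_low < e.estimate < e.ci_high

    def test_small_b_warns(self, tiny_pheno):
        table, _, _ = tiny_pheno
        with pytest.warns(UserWarning, match="bootstrap"):
            bootstrap_inference(table, "glucose_mg_dl", B=50, seed=1)


class TestHeritableShare:
    def test_zero_when_fits_identical(self, tiny_pheno):
        table, _, _ = tiny_pheno
        full = fit_sex_model(table, "M", "glucose_mg_dl", True)
        share = heritable_share(full, full)
        assert share.proportion == pytest.approx(0.0)

    def test_pure_interaction_truth_near_one(self):
        # XOR-like architecture: no main effects, large interaction
        cfg = PhenoSimConfig(
            maternal_panel=("3",), paternal_panel=("4",), exclusions=(),
            cell_sizes=(100, 100, 100),
            main_effects={"glucose_mg_dl": {
                "M": {"3": 30.0, "4": 30.0}, "F": {"3": 30.0, "4": 30.0}}},
            interaction_effects={"glucose_mg_dl": {
                "M": {("3", "4"): -60.0}, "F": {("3", "4"): -60.0}}},
            residual_sd={"F": {"body_weight_g": 1e-6, "glucose_mg_dl": 1e-6},
                         "M": {"body_weight_g": 1e-6, "glucose_mg_dl": 1e-6}},
            outlier_rate=0.0, seed=6,
        )
        table, _ = simulate_phenotypes(cfg)
        full = fit_sex_model(table, "M", "glucose_mg_dl", True)
        add = fit_sex_model(table, "M", "glucose_mg_dl", False)
        share = heritable_share(full, add)
        assert share.proportion == pytest.approx(1.0, abs=0.01)

    def test_undefined_when_no_heritable_variation(self):
        cfg = PhenoSimConfig(maternal_panel=("3",), paternal_panel=("4",),
                             exclusions=(), cell_sizes=(10, 10, 10),
                             outlier_rate=0.0, seed=7)
        table, _ = simulate_phenotypes(cfg)
        full = fit_sex_model(table, "M", "glucose_mg_dl", True)
        add = fit_sex_model(table, "M", "glucose_mg_dl", False)
        share = heritable_share(full, add)
        if full.r2_adj <= 0:
            assert not share.defined


class TestAnalyzeTrait:
    def test_end_to_end_contents(self, tiny_pheno):
        table, _, _ = tiny_pheno
        res = analyze_trait(table, "glucose_mg_dl", winsorize_k=4, B=400,
                            seed=0)
        assert res.winsorization is not None
        assert set(res.joint["sex"]) == {"F", "M", "meta"}
        meta_int = res.joint[(res.joint.sex == "meta")
                             & (res.joint.term_class == "interaction")]
        assert float(meta_int["p"].iloc[0]) < 0.05
        assert res.bootstrap.n_significant("interaction") >= 1
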