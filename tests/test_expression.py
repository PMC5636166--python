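import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cssmap.design import build_design_matrix
from cssmap.expression import (
    estimate_surrogates,
    filter_genes,
    fit_expression_models,
    fit_gene_model,
    qc_samples,
)
from cssmap.glm import fit_nb_glm, squeeze_var
from cssmap.simulate import ExprDataset, ExprSimConfig, simulate_counts


def small_dataset(seed=2, **kw):
    base = dict(n_genes=250, maternal_panel=("3", "6"), paternal_panel=("4", "8"),
                exclusions=(), replicates=(12, 8, 6), seed=seed)
    base.update(kw)
    return simulate_counts(ExprSimConfig(**base))


class TestQC:
    def test_homogeneous_dataset_zero_flags(self):
        ds, _ = small_dataset(seed=3, n_batch=0, cis_prob=0, trans_prob=0,
                              interaction_prob=0)
        _, flagged = qc_samples(ds)
        assert flagged == []

    def test_permuted_sample_flagged(self):
        ds, _ = small_dataset(seed=4, n_genes=300)
        rng = np.random.default_rng(0)
        bad = ds.counts.columns[7]
        ds.counts[bad] = rng.permutation(ds.counts[bad].to_numpy())
        kept, flagged = qc_samples(ds)
        assert bad in flagged
        assert bad not in kept.counts.columns

    def test_deterministic(self):
        ds, _ = small_dataset(seed=5)
        _, f1 = qc_samples(ds)
        _, f2 = qc_samples(ds)
        assert f1 == f2

    def test_systemic_problem_raises(self):
        ds, _ = small_dataset(seed=6, n_genes=120)
        rng = np.random.default_rng(1)
        for s in ds.counts.columns[::3]:
            ds.counts[s] = rng.permutation(ds.counts[s].to_numpy())
        with pytest.raises(ValueError, match="systemic"):
            qc_samples(ds)


class TestFilter:
    @staticmethod
    def _dataset_from_counts(rows):
        counts = pd.DataFrame(rows, index=[f"g{i}" for i in range(len(rows))])
        counts.columns = [f"s{i}" for i in range(counts.shape[1])]
        samples = pd.DataFrame(
            {"maternal_sub": [None] * counts.shape[1],
             "paternal_sub": [None] * counts.shape[1]},
            index=counts.columns,
        )
        chrom = pd.Series("1", index=counts.index)
        return ExprDataset(counts=counts, samples=samples, gene_chrom=chrom)

    def test_boundary_75_percent_kept(self):
        # 6 of 8 samples at >= 15 is exactly 75%: kept
        ds = self._dataset_from_counts([[15, 15, 15, 15, 15, 15, 0, 0]])
        assert filter_genes(ds).n_genes == 1

    def test_below_boundary_removed(self):
        ds = self._dataset_from_counts([[15, 15, 15, 15, 15, 0, 0, 0]])
        assert filter_genes(ds).n_genes == 0

    def test_threshold_value_inclusive(self):
        kept = self._dataset_from_counts([[15] * 8])
        removed = self._dataset_from_counts([[14] * 8])
        assert filter_genes(kept).n_genes == 1
        assert filter_genes(removed).n_genes == 0


class TestSurrogates:
    def test_planted_batch_factor_recovered(self):
        # build counts with one latent factor by hand
        rng = np.random.default_rng(10)
        n_genes, n_samples = 400, 60
        z = rng.normal(size=n_samples)
        lam = rng.normal(0, 0.5, size=n_genes) * (rng.random(n_genes) < 0.5)
        eta = rng.normal(5, 1, n_genes)[:, None] + lam[:, None] * z[None, :]
        counts = pd.DataFrame(
            rng.poisson(np.exp(eta)),
            index=[f"g{i}" for i in range(n_genes)],
            columns=[f"s{i}" for i in range(n_samples)],
        )
        samples = pd.DataFrame(
            {"maternal_sub": ["3"] * 30 + [None] * 30,
             "paternal_sub": [None] * 60},
            index=counts.columns,
        )
        ds = ExprDataset(counts=counts, samples=samples,
                         gene_chrom=pd.Series("1", index=counts.index))
        sv = estimate_surrogates(ds, build_design_matrix(samples), k=3)
        r = abs(np.corrcoef(sv["SV1"], z)[0, 1])
        assert r > 0.9

    def test_no_batch_effects_adjustment_is_negligible(self):
        ds, _ = small_dataset(seed=7, n_genes=120, n_batch=0,
                              cis_prob=0.3, interaction_prob=0.0)
        ds = filter_genes(ds)
        dm = build_design_matrix(ds.samples)
        sv = estimate_surrogates(ds, dm, k=5)
        f_adj = fit_expression_models(ds, covariates=sv)
        f_raw = fit_expression_models(ds, covariates=None)
        terms = dm.main_terms
        deltas = [
            abs(f_adj[g].params[t] - f_raw[g].params[t])
            for g in f_adj.fits if g in f_raw.fits for t in terms
        ]
        assert np.median(deltas) < 0.05

    def test_sign_convention_deterministic(self):
        ds, _ = small_dataset(seed=8)
        dm = build_design_matrix(ds.samples)
        sv1 = estimate_surrogates(ds, dm, k=4)
        sv2 = estimate_surrogates(ds, dm, k=4)
        pd.testing.assert_frame_equal(sv1, sv2)

    def test_k_exceeding_residual_rank_rejected(self):
        ds, _ = small_dataset(seed=9, replicates=(3, 1, 1))
        dm = build_design_matrix(ds.samples)
        with pytest.raises(ValueError, match="residual rank"):
            estimate_surrogates(ds, dm, k=ds.n_samples)


class TestGeneModel:
    def test_constant_gene_null_coefficients(self):
        ds, _ = small_dataset(seed=12, n_genes=30, cis_prob=0, trans_prob=0,
                              interaction_prob=0, n_batch=0,
                              dispersion=(1e-9, 0), dispersion_trend_scale=0,
                              lib_size_log10_sd=0.0)
        ds = filter_genes(ds)
        g = ds.counts.index[0]
        fit = fit_gene_model(ds, gene=g)
        genetic = [c for c in fit.params.index if c != "Intercept"]
        assert np.all(np.abs(fit.params[genetic]) < 0.5)
        assert fit.tests["all_strain"][3] > 0.01

    def test_matches_statsmodels_nb_glm(self):
        import statsmodels.api as sm

        ds, _ = small_dataset(seed=13, n_genes=40, cis_prob=0.5)
        ds = filter_genes(ds)
        dm = build_design_matrix(ds.samples)
        X = dm.X.to_numpy(float)
        offset = np.log(ds.lib_sizes.to_numpy(float))
        phi = 0.07
        for g in ds.counts.index[:5]:
            y = ds.counts.loc[g].to_numpy(float)
            mine = fit_nb_glm(y, X, offset, dispersion=phi)
            ref = sm.GLM(
                y, X, family=sm.families.NegativeBinomial(alpha=phi),
                offset=offset,
            ).fit()
            np.testing.assert_allclose(mine.beta, ref.params, atol=1e-6)

    def test_planted_cis_effect_recovered(self):
        # 2-fold effect, 12 control vs 8 single samples
        hits = 0
        reps = 40
        for r in range(reps):
            rng = np.random.default_rng(100 + r)
            n0, n1 = 12, 8
            mu0 = 200.0
            lfc = np.log(2.0)
            phi = 0.05
            y = np.concatenate([
                rng.poisson(mu0 * rng.gamma(1 / phi, phi, n0)),
                rng.poisson(mu0 * np.exp(lfc) * rng.gamma(1 / phi, phi, n1)),
            ]).astype(float)
            X = np.column_stack([np.ones(n0 + n1),
                                 np.r_[np.zeros(n0), np.ones(n1)]])
            fit = fit_nb_glm(y, X, 0.0, dispersion=phi)
            se = np.sqrt(fit.cov_unscaled[1, 1])
            if abs(fit.beta[1] - lfc) <= 1.96 * se:
                hits += 1
        assert hits / reps >= 0.9

    def test_global_null_poisson_calibration(self):
        ds, _ = small_dataset(
            seed=14, n_genes=500, cis_prob=0, trans_prob=0,
            interaction_prob=0, n_batch=0, dispersion=(1e-9, 0),
            dispersion_trend_scale=0,
        )
        ds = filter_genes(ds)
        fits = fit_expression_models(ds)
        p = [f.tests["all_strain"][3] for f in fits]
        assert stats.kstest(p, "uniform").pvalue > 0.01

    def test_offset_absorbs_library_rescaling(self):
        ds, _ = small_dataset(seed=15, n_genes=20)
        ds = filter_genes(ds)
        g = ds.counts.index[0]
        fit1 = fit_gene_model(ds, gene=g, dispersion=0.05)
        ds2 = ExprDataset(counts=ds.counts, samples=ds.samples,
                          gene_chrom=ds.gene_chrom,
                          lib_sizes=ds.lib_sizes * 2.0)
        fit2 = fit_gene_model(ds2, gene=g, dispersion=0.05)
        keep = [c for c in fit1.params.index if c != "Intercept"]
        np.testing.assert_allclose(fit1.params[keep], fit2.params[keep],
                                   atol=1e-6)
        assert fit2.params["Intercept"] == pytest.approx(
            fit1.params["Intercept"] - np.log(2.0), abs=1e-6
        )

    def test_dispersion_shrinkage_reduces_spread(self, expr_fitted):
        ds, _, fits = expr_fitted
        from cssmap.glm import estimate_dispersion

        dm = build_design_matrix(ds.samples)
        X = dm.X.to_numpy(float)
        offset = np.log(ds.lib_sizes.to_numpy(float))
        genes = fits.genes()[:40]
        raw = np.log([
            max(estimate_dispersion(ds.counts.loc[g].to_numpy(float), X,
                                    offset), 1e-6)
            for g in genes
        ])
        shrunk = np.log([max(fits[g].dispersion, 1e-6) for g in genes])
        assert np.std(shrunk) < np.std(raw)

    def test_squeeze_var_pulls_toward_prior(self):
        rng = np.random.default_rng(3)
        df = 20
        s2 = rng.chisquare(df, 200) / df * 2.0
        post, d0, s0 = squeeze_var(s2, df)
        assert np.var(post) < np.var(s2)
        assert d0 > 0 and s0 > 0

    def test_additive_fitted_matches_full_when_no_interaction(self):
        ds, _ = small_dataset(seed=16, n_genes=150, cis_prob=0.4,
                              trans_prob=0.0, interaction_prob=0.0,
                              n_batch=0, replicates=(60, 40, 30),
                              dispersion=(0.02, 0), dispersion_trend_scale=0)
        ds = filter_genes(ds)
        fits = fit_expression_models(ds)
        rel = []
        for f in fits:
            fv_f = f.fitted_full.to_numpy()
            fv_a = f.fitted_additive.to_numpy()
            rel.append(np.median(np.abs(fv_f - fv_a) / np.maximum(fv_a, 1)))
        assert np.median(rel) < 0.05
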