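"""Expression pipeline core: sample QC, gene filtering, surrogate covariates,
and per-gene negative-binomial interaction models with moderated tests.

The per-gene model is a log-link NB GLM of counts on the CSS design (maternal
main effects, paternal main effects, maternal x paternal interactions), plus
surrogate covariates and a log-library-size offset, so departure from
additivity on the link scale is departure from a multiplicative model on the
expression level.  Dispersions are estimated per gene by Cox-Reid adjusted
profile likelihood and shrunk toward a lowess mean-dispersion trend; per-term
and joint tests use empirical-Bayes moderated quasi-likelihood F statistics.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, build_design_matrix
from .glm import NBFit, estimate_dispersion, fit_nb_glm, squeeze_var, ql_f_test
from .simulate import ExprDataset

__all__ = [
    "ExprDataset",
    "GeneFit",
    "ExpressionFits",
    "log_cpm",
    "qc_samples",
    "filter_genes",
    "estimate_surrogates",
    "fit_gene_model",
    "fit_expression_models",
]

log = logging.getLogger(__name__)


def log_cpm(dataset: ExprDataset, prior: float = 0.5) -> pd.DataFrame:
    """log2 counts per million with a small prior count (genes x samples)."""
    lib = dataset.lib_sizes.to_numpy(float)
    cpm = (dataset.counts.to_numpy(float) + prior) / (lib + 2 * prior) * 1e6
    return pd.DataFrame(np.log2(cpm), index=dataset.counts.index,
                        columns=dataset.counts.columns)


# ---------------------------------------------------------------------------
# sample QC

def qc_samples(
    dataset: ExprDataset,
    n_mads: float = 5.0,
    min_drop: float = 0.05,
    max_flag_frac: float = 0.2,
) -> tuple[ExprDataset, list[str]]:
    """Flag and remove outlier samples by pairwise expression correlation.

    A sample is flagged when its median pairwise Spearman correlation (of
    log-scaled normalized counts against all other samples) falls more than
    ``n_mads`` raw median-absolute-deviations -- and at least ``min_drop``
    correlation units -- below the cohort median of that quantity.  The
    absolute floor keeps the rule from firing on cohorts whose correlations
    are so homogeneous that the MAD is nearly zero.  Flagging more than
    ``max_flag_frac`` of samples is treated as a systemic problem and raises.
    """
    if dataset.n_samples < 4:
        raise ValueError("sample QC needs at least 4 samples")
    lc = log_cpm(dataset)
    corr = stats.spearmanr(lc.to_numpy()).statistic
    corr = np.atleast_2d(corr)
    np.fill_diagonal(corr, np.nan)
    med_corr = np.nanmedian(corr, axis=0)
    center = np.median(med_corr)
    mad = np.median(np.abs(med_corr - center))
    cutoff = center - max(n_mads * mad, min_drop)
    flagged = [s for s, v in zip(lc.columns, med_corr) if v < cutoff]
    if len(flagged) > max_flag_frac * dataset.n_samples:
        raise ValueError(
            f"{len(flagged)}/{dataset.n_samples} samples flagged as outliers; "
            "this points at a systemic problem, not individual outliers"
        )
    if not flagged:
        return dataset, []
    keep = [s for s in dataset.counts.columns if s not in flagged]
    return dataset.subset_samples(keep), flagged


def filter_genes(
    dataset: ExprDataset,
    min_count: int = 15,
    min_frac: float = 0.75,
) -> ExprDataset:
    """Remove low-expressed genes.

    A gene is kept iff at least ``min_frac`` of samples have a count of at
    least ``min_count`` (boundary inclusive: exactly 75% of samples at or
    above the threshold keeps the gene).
    """
    frac = (dataset.counts.to_numpy() >= min_count).mean(axis=1)
    keep = dataset.counts.index[frac >= min_frac]
    return dataset.subset_genes(keep)


# ---------------------------------------------------------------------------
# surrogate covariates (residual PCA)

def _signed_pcs(M: np.ndarray, k: int) -> np.ndarray:
    """Top-k left singular vectors (samples x k) with a fixed sign convention
    (largest-magnitude sample loading positive)."""
    U, _, _ = np.linalg.svd(M, full_matrices=False)
    sv = U[:, :k].copy()
    for j in range(k):
        i = np.argmax(np.abs(sv[:, j]))
        if sv[i, j] < 0:
            sv[:, j] = -sv[:, j]
    return sv


def estimate_surrogates(
    dataset: ExprDataset,
    design: DesignMatrix | pd.DataFrame,
    k: int = 5,
    method: str = "null-genes",
    null_p: float = 0.5,
) -> pd.DataFrame:
    """Estimate k surrogate covariates capturing latent batch structure.

    ``method="null-genes"`` (default): per-gene F-tests of the design on
    log-scaled normalized counts identify genes with no evidence of genetic
    regulation (p > ``null_p``); the surrogates are the top ``k`` principal
    components of the centered log expression of those genes.  Because the
    null genes carry the batch factors in full, this retains the component of
    a batch factor that is incidentally correlated with the design -- removing
    only the design-orthogonal part (plain residual PCA) leaves that
    component to contaminate the genetic coefficients.

    ``method="residual"``: principal components of the residual matrix after
    projecting design-explained variation out of every gene; kept as the
    simpler alternative (and the fallback when too few null genes exist).

    Returns a samples x k frame of unit-norm covariates with a deterministic
    sign convention (largest-magnitude sample loading positive).
    """
    X = design.X if isinstance(design, DesignMatrix) else design
    Xv = X.to_numpy(float)
    rank = np.linalg.matrix_rank(Xv)
    n = dataset.n_samples
    resid_rank = n - rank
    if k >= resid_rank:
        raise ValueError(
            f"k = {k} surrogate variables exceed the residual rank {resid_rank}"
        )
    Y = log_cpm(dataset).to_numpy()  # genes x samples
    Q, _ = np.linalg.qr(Xv)
    fitted = (Y @ Q) @ Q.T
    R = Y - fitted

    sv = None
    if method == "null-genes":
        # per-gene design F-test on the log scale
        ybar = Y.mean(axis=1, keepdims=True)
        ss_model = np.sum((fitted - ybar) ** 2, axis=1)
        ss_resid = np.sum(R**2, axis=1)
        df1, df2 = rank - 1, n - rank
        with np.errstate(divide="ignore", invalid="ignore"):
            F = (ss_model / df1) / (ss_resid / df2)
        pvals = stats.f.sf(F, df1, df2)
        null_genes = np.flatnonzero(pvals > null_p)
        if null_genes.size >= max(10 * k, 50):
            Yn = Y[null_genes]
            Yn = Yn - Yn.mean(axis=1, keepdims=True)
            sv = _signed_pcs(Yn.T, k)
        else:
            warnings.warn(
                f"only {null_genes.size} design-null genes; "
                "falling back to residual PCA surrogates"
            )
    elif method != "residual":
        raise ValueError(f"unknown surrogate method {method!r}")
    if sv is None:
        Rc = R - R.mean(axis=1, keepdims=True)
        sv = _signed_pcs(Rc.T, k)
    return pd.DataFrame(
        sv, index=dataset.counts.columns,
        columns=[f"SV{i + 1}" for i in range(k)],
    )


# ---------------------------------------------------------------------------
# per-gene models

@dataclass
class GeneFit:
    """Moderated NB-GLM fit of a single gene."""

    gene: str
    params: pd.Series               # log-scale coefficients (full model)
    cov: pd.DataFrame               # QL-scaled covariance for contrasts
    dispersion: float
    s2_post: float                  # squeezed QL dispersion
    df_total: float                 # residual df + prior df
    df_resid: int
    fitted_full: pd.Series
    fitted_additive: pd.Series
    params_additive: pd.Series
    tests: dict = field(default_factory=dict)  # name -> (F, df1, df2, p)
    converged: bool = True

    def test_p(self, name: str) -> float:
        return self.tests[name][3]


@dataclass
class ExpressionFits:
    """Container for all per-gene fits plus shared design information."""

    fits: dict
    design: DesignMatrix
    covariates: pd.DataFrame | None
    offset: pd.Series
    prior_df: float
    prior_s2: float
    failed: list = field(default_factory=list)

    def __iter__(self):
        return iter(self.fits.values())

    def __getitem__(self, gene: str) -> GeneFit:
        return self.fits[gene]

    def genes(self) -> list[str]:
        return list(self.fits)

    def p_frame(self, test: str) -> pd.Series:
        return pd.Series({g: f.tests[test][3] for g, f in self.fits.items()},
                         name=test)


def _dispersion_trend(log_mean: np.ndarray, log_phi: np.ndarray) -> np.ndarray:
    """Lowess trend of log dispersion on log mean (flat fallback at n < 10)."""
    if log_mean.size < 10:
        return np.full_like(log_phi, np.median(log_phi))
    from statsmodels.nonparametric.smoothers_lowess import lowess

    sm = lowess(log_phi, log_mean, frac=0.5, it=1, return_sorted=False)
    return sm


def _design_for(dataset: ExprDataset,
                covariates: pd.DataFrame | None) -> tuple[DesignMatrix, pd.DataFrame]:
    dm = build_design_matrix(dataset.samples, include_interactions=True)
    X = dm.X
    if covariates is not None:
        X = pd.concat([X, covariates.loc[X.index]], axis=1)
    return dm, X


def fit_expression_models(
    dataset: ExprDataset,
    covariates: pd.DataFrame | None = None,
    prior_df: float = 10.0,
    dispersion: float | None = None,
) -> ExpressionFits:
    """Fit the full interaction NB GLM to every gene with moderated tests.

    Steps: per-gene Cox-Reid dispersion, shrinkage toward the lowess
    mean-dispersion trend with weight prior_df / (prior_df + df_resid), full
    and reduced (additive; intercept + covariates) fits at the shrunk
    dispersion, empirical-Bayes squeezing of the per-gene QL dispersions, and
    moderated F tests: one per genetic term (Wald), the all-strain joint null
    and the all-interactions joint null (deviance based).  Non-converged
    genes are recorded in ``failed`` and excluded from ``fits``.
    """
    dm, Xfull_df = _design_for(dataset, covariates)
    Xfull = Xfull_df.to_numpy(float)
    genes = list(dataset.counts.index)
    counts = dataset.counts.to_numpy(float)
    offset = np.log(dataset.lib_sizes.to_numpy(float))
    n, p = Xfull.shape
    df_resid = n - p

    int_cols = [Xfull_df.columns.get_loc(c) for c in dm.interaction_terms]
    genetic_cols = [
        Xfull_df.columns.get_loc(c)
        for c in dm.X.columns if c != "Intercept"
    ]
    add_idx = [j for j in range(p) if j not in int_cols]
    null_idx = [j for j in range(p) if j not in genetic_cols]

    if dispersion is None:
        phis = np.array([
            estimate_dispersion(counts[i], Xfull, offset)
            for i in range(len(genes))
        ])
        log_mean = np.log(counts.mean(axis=1) + 0.5)
        trend = _dispersion_trend(log_mean, np.log(phis))
        w = prior_df / (prior_df + df_resid)
        phis = np.exp(w * trend + (1 - w) * np.log(phis))
    else:
        phis = np.full(len(genes), float(dispersion))

    full_fits: list[NBFit | None] = []
    add_fits: list[NBFit | None] = []
    null_devs = np.empty(len(genes))
    s2 = np.empty(len(genes))
    for i in range(len(genes)):
        ff = fit_nb_glm(counts[i], Xfull, offset, phis[i])
        fa = fit_nb_glm(counts[i], Xfull[:, add_idx], offset, phis[i])
        f0 = fit_nb_glm(counts[i], Xfull[:, null_idx], offset, phis[i])
        if not (ff.converged and fa.converged and f0.converged):
            full_fits.append(None)
            add_fits.append(None)
            null_devs[i] = np.nan
            s2[i] = np.nan
            continue
        full_fits.append(ff)
        add_fits.append(fa)
        null_devs[i] = f0.deviance
        s2[i] = ff.deviance / df_resid

    s2_post, d0, s0 = squeeze_var(s2[np.isfinite(s2)], df_resid) if np.any(
        np.isfinite(s2)) else (s2, 1e6, 1.0)
    post = np.full(len(genes), np.nan)
    post[np.isfinite(s2)] = s2_post
    df_total = df_resid + min(d0, 1e6)

    fits: dict[str, GeneFit] = {}
    failed: list[str] = []
    cols = list(Xfull_df.columns)
    genetic_terms = [c for c in dm.X.columns if c != "Intercept"]
    for i, g in enumerate(genes):
        ff = full_fits[i]
        if ff is None:
            failed.append(g)
            log.warning("gene %s: NB GLM did not converge; excluded", g)
            continue
        fa = add_fits[i]
        cov = pd.DataFrame(ff.cov_unscaled * post[i], index=cols, columns=cols)
        params = pd.Series(ff.beta, index=cols)
        tests = {}
        # joint tests from deviance drops
        F, pv = ql_f_test(null_devs[i], ff.deviance, len(genetic_cols),
                          post[i], df_total)
        tests["all_strain"] = (F, len(genetic_cols), df_total, pv)
        if int_cols:
            F, pv = ql_f_test(fa.deviance, ff.deviance, len(int_cols),
                              post[i], df_total)
            tests["all_interaction"] = (F, len(int_cols), df_total, pv)
        # per-term moderated Wald F
        for t in genetic_terms:
            j = cols.index(t)
            se = np.sqrt(cov.iloc[j, j])
            Ft = (ff.beta[j] / se) ** 2 if se > 0 else np.nan
            tests[t] = (float(Ft), 1, df_total,
                        float(stats.f.sf(Ft, 1, df_total)))
        fits[g] = GeneFit(
            gene=g,
            params=params,
            cov=cov,
            dispersion=float(phis[i]),
            s2_post=float(post[i]),
            df_total=float(df_total),
            df_resid=df_resid,
            fitted_full=pd.Series(ff.mu, index=Xfull_df.index),
            fitted_additive=pd.Series(fa.mu, index=Xfull_df.index),
            params_additive=pd.Series(fa.beta, index=[cols[j] for j in add_idx]),
            tests=tests,
        )
    return ExpressionFits(
        fits=fits, design=dm, covariates=covariates,
        offset=pd.Series(offset, index=Xfull_df.index),
        prior_df=float(d0), prior_s2=float(s0), failed=failed,
    )


def fit_gene_model(
    dataset: ExprDataset,
    design: DesignMatrix | None = None,
    covariates: pd.DataFrame | None = None,
    gene: str | None = None,
    dispersion: float | None = None,
) -> GeneFit:
    """Fit the interaction model for a single gene.

    Convenience wrapper over :func:`fit_expression_models` semantics for one
    gene: the dispersion is estimated from that gene alone (no trend
    shrinkage, no variance squeezing) unless given.
    """
    if gene is None:
        raise ValueError("gene id required")
    sub = dataset.subset_genes([gene])
    fits = fit_expression_models(sub, covariates=covariates,
                                 dispersion=dispersion)
    if gene in fits.fits:
        return fits[gene]
    raise RuntimeError(f"gene {gene}: model did not converge")
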