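"""Trait pipeline for CSS crosses.

Per sex, an ordinary least squares model with maternal, paternal and pairwise
interaction indicator terms (reference = control strain) is fit to each trait
after a one-sided winsorization of the pooled trait vector.  Sexes are
combined per term by inverse-variance weighting (IVW); joint F-tests per term
class are combined across sexes with Fisher's method.  Inference that is
robust to non-normality and heteroscedasticity comes from a studentized
bootstrap that resamples animals with replacement within every cross x sex
cell, with family-wise error control by comparison to the maximum bootstrap
statistic (maxT) separately for the main-effect and interaction families.
The share of heritable variation attributable to interactions is
(R2adj_full - R2adj_additive) / R2adj_full.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .design import DesignMatrix, build_design_matrix, remove_small_cells

__all__ = [
    "WinsorizeResult",
    "SexFit",
    "MetaEffect",
    "HeritableShare",
    "winsorize",
    "fit_sex_model",
    "fit_combined_sex_model",
    "joint_test",
    "fisher_combine",
    "ivw_combine",
    "bootstrap_inference",
    "heritable_share",
    "analyze_trait",
]


# ---------------------------------------------------------------------------
# winsorization

@dataclass
class WinsorizeResult:
    values: np.ndarray
    ceiling: float
    n_modified: int
    center: float
    scale: float  # raw (unscaled) MAD
    #: the ceiling under the 1.4826-scaled MAD convention, for comparison
    ceiling_scaled: float = np.nan


def winsorize(values, k: float = 4.0) -> WinsorizeResult:
    """Cap values above median + k * MAD (raw, unscaled MAD); no floor.

    Values are capped at the ceiling, never removed; entries below the
    ceiling are untouched, so the operation is idempotent and order
    preserving below the ceiling.  All-identical input (MAD = 0) degenerates
    to ceiling = median with a warning.
    """
    x = np.asarray(values, dtype=float)
    finite = x[np.isfinite(x)]
    if finite.size < 3:
        raise ValueError("winsorize needs at least 3 finite values")
    med = float(np.median(finite))
    mad = float(np.median(np.abs(finite - med)))
    if mad == 0.0:
        warnings.warn("MAD is zero (all values identical?); ceiling = median")
    ceiling = med + k * mad
    out = np.where(np.isfinite(x) & (x > ceiling), ceiling, x)
    n_mod = int(np.sum(np.isfinite(x) & (x > ceiling)))
    return WinsorizeResult(
        values=out,
        ceiling=ceiling,
        n_modified=n_mod,
        center=med,
        scale=mad,
        ceiling_scaled=med + k * 1.4826 * mad,
    )


# ---------------------------------------------------------------------------
# per-sex linear models

@dataclass
class SexFit:
    """OLS fit of one trait in one sex on the CSS design."""

    sex: str
    trait: str
    params: pd.Series
    cov: pd.DataFrame
    df_resid: float
    nobs: int
    r2: float
    r2_adj: float
    design: DesignMatrix
    y: np.ndarray

    @property
    def bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov)), index=self.params.index)

    def terms_of_class(self, term_class: str) -> list[str]:
        return self.design.terms_of_class(term_class)


def _ols(X: pd.DataFrame, y: np.ndarray) -> tuple[pd.Series, pd.DataFrame, float, float, float]:
    import statsmodels.api as sm

    res = sm.OLS(y, X).fit()
    return (
        res.params,
        pd.DataFrame(res.cov_params(), index=X.columns, columns=X.columns),
        float(res.df_resid),
        float(res.rsquared),
        float(res.rsquared_adj),
    )


def _prepare_sex_table(table: pd.DataFrame, sex: str, trait: str,
                       min_cell: int | None) -> pd.DataFrame:
    sub = table[table["sex"] == sex]
    sub = sub[np.isfinite(pd.to_numeric(sub[trait], errors="coerce"))]
    if min_cell:
        sub, _ = remove_small_cells(sub, min_cell=min_cell, by_sex=True)
    return sub


def fit_sex_model(
    table: pd.DataFrame,
    sex: str,
    trait: str,
    with_interactions: bool = True,
    min_cell: int | None = 5,
) -> SexFit:
    """OLS fit of ``trait`` for one sex on the CSS design.

    Animals with a missing trait value and animals in cross x sex cells
    smaller than ``min_cell`` are dropped first; the design is rebuilt from
    the retained animals so interaction columns exist only for observed
    pairs.  Returns coefficient vector, OLS covariance, and both coefficients
    of determination.
    """
    sub = _prepare_sex_table(table, sex, trait, min_cell)
    dm = build_design_matrix(sub, include_interactions=with_interactions)
    if len(sub) <= dm.X.shape[1]:
        raise ValueError(
            f"{len(sub)} observations for {trait}/{sex} cannot support "
            f"{dm.X.shape[1]} parameters"
        )
    y = pd.to_numeric(sub[trait]).to_numpy(float)
    params, cov, df_resid, r2, r2_adj = _ols(dm.X, y)
    return SexFit(sex, trait, params, cov, df_resid, len(sub), r2, r2_adj, dm, y)


def fit_combined_sex_model(
    table: pd.DataFrame,
    trait: str,
    with_interactions: bool = True,
    min_cell: int | None = 5,
) -> SexFit:
    """Single model over both sexes with a sex indicator covariate.

    Genetic effects are constrained equal across sexes; provided as the
    alternative to the per-sex + IVW route.
    """
    sub = table[np.isfinite(pd.to_numeric(table[trait], errors="coerce"))]
    if min_cell:
        sub, _ = remove_small_cells(sub, min_cell=min_cell, by_sex=True)
    sexes = set(sub["sex"])
    if len(sexes) < 2:
        raise ValueError(f"combined-sex model needs both sexes, got {sexes}")
    dm = build_design_matrix(sub, include_interactions=with_interactions)
    X = dm.X.copy()
    X.insert(1, "sexM", (sub["sex"] == "M").astype(float).to_numpy())
    dm2 = DesignMatrix(
        X=X,
        term_classes={**{"sexM": "covariate"}, **dm.term_classes},
        crosses=dm.crosses,
    )
    y = pd.to_numeric(sub[trait]).to_numpy(float)
    params, cov, df_resid, r2, r2_adj = _ols(X, y)
    return SexFit("FM", trait, params, cov, df_resid, len(sub), r2, r2_adj, dm2, y)


def joint_test(fit: SexFit, term_class: str) -> tuple[float, int, float, float]:
    """Joint F-test that all coefficients of a term class are zero.

    ``term_class`` is ``"main"`` (all maternal + paternal indicators) or
    ``"interaction"``.  Returns (F, df1, df2, p); the Wald quadratic form on
    the OLS covariance, which equals the nested residual-sum-of-squares F.
    """
    terms = fit.terms_of_class(term_class)
    if not terms:
        raise ValueError(f"no terms of class {term_class!r} in fit")
    beta = fit.params[terms].to_numpy()
    V = fit.cov.loc[terms, terms].to_numpy()
    q = len(terms)
    F = float(beta @ np.linalg.solve(V, beta)) / q
    p = float(stats.f.sf(F, q, fit.df_resid))
    return F, q, fit.df_resid, p


# ---------------------------------------------------------------------------
# cross-sex combination

def fisher_combine(pvals) -> float:
    """Fisher's method: -2 sum(ln p) ~ chi-square with 2k df."""
    p = np.asarray(list(pvals), dtype=float)
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    stat = -2.0 * np.sum(np.log(p))
    return float(stats.chi2.sf(stat, 2 * p.size))


def ivw_combine(beta_f: float, var_f: float, beta_m: float, var_m: float
                ) -> tuple[float, float, float]:
    """Inverse-variance weighted combination of female and male estimates.

    Returns (combined estimate, combined variance, weight w on the female
    estimate): beta = w * beta_f + (1 - w) * beta_m with
    w = (1/var_f) / (1/var_f + 1/var_m).
    """
    if var_f <= 0 or var_m <= 0:
        raise ValueError("variances must be positive")
    wf = 1.0 / var_f
    wm = 1.0 / var_m
    w = wf / (wf + wm)
    return w * beta_f + (1 - w) * beta_m, 1.0 / (wf + wm), w


# ---------------------------------------------------------------------------
# studentized bootstrap with maxT family-wise adjustment

@dataclass
class MetaEffect:
    term: str
    term_class: str
    estimate: float          # IVW-combined
    variance: float
    weight_f: float          # weight on the female estimate
    se: float = np.nan
    statistic: float = np.nan
    raw_p: float = np.nan
    adj_p: float = np.nan
    ci_low: float = np.nan
    ci_high: float = np.nan
    beta_f: float = np.nan
    beta_m: float = np.nan


@dataclass
class HeritableShare:
    """Interaction share of heritable variation for one sex."""

    sex: str
    proportion: float
    r2_adj_full: float
    r2_adj_additive: float
    ci_low: float = np.nan
    ci_high: float = np.nan
    defined: bool = True


def heritable_share(fit_full: SexFit, fit_add: SexFit) -> HeritableShare:
    """(R2adj_full - R2adj_additive) / R2adj_full; unclipped.

    Undefined (flagged) when R2adj_full <= 0: there is no heritable variation
    to apportion.
    """
    if fit_full.nobs != fit_add.nobs:
        raise ValueError("full and additive fits must use identical observations")
    rf, ra = fit_full.r2_adj, fit_add.r2_adj
    if rf <= 0:
        return HeritableShare(fit_full.sex, np.nan, rf, ra, defined=False)
    return HeritableShare(fit_full.sex, (rf - ra) / rf, rf, ra)


class _SexData:
    """Pre-extracted arrays for fast repeated weighted fits of one sex."""

    def __init__(self, table: pd.DataFrame, sex: str, trait: str,
                 min_cell: int | None):
        sub = _prepare_sex_table(table, sex, trait, min_cell)
        self.dm = build_design_matrix(sub, include_interactions=True)
        self.X = self.dm.X.to_numpy(float)
        self.columns = list(self.dm.X.columns)
        self.y = pd.to_numeric(sub[trait]).to_numpy(float)
        self.n, self.p = self.X.shape
        X_add_cols = [c for c in self.columns
                      if self.dm.term_classes[c] != "interaction"]
        self.add_idx = np.array([self.columns.index(c) for c in X_add_cols])
        # cross cells for within-cell resampling
        codes, _ = pd.factorize(self.dm.crosses.map(str))
        self.cells = [np.flatnonzero(codes == c) for c in range(codes.max() + 1)]
        for cell in self.cells:
            if cell.size == 1:
                warnings.warn(
                    f"cell of size 1 in sex {sex}: degenerate bootstrap resample"
                )

    def fit_weighted(self, w: np.ndarray):
        """Weighted OLS == OLS on the resampled (expanded) data set."""
        Xw = self.X * w[:, None]
        A = self.X.T @ Xw
        beta = np.linalg.solve(A, Xw.T @ self.y)
        resid = self.y - self.X @ beta
        rss = float(w @ resid**2)
        sigma2 = rss / (self.n - self.p)
        cov = sigma2 * np.linalg.inv(A)
        # weighted R2 (adjusted) against the weighted mean
        ybar = float(w @ self.y) / self.n
        tss = float(w @ (self.y - ybar) ** 2)
        r2 = 1.0 - rss / tss
        r2_adj = 1.0 - (1.0 - r2) * (self.n - 1) / (self.n - self.p)
        # additive submodel for the share
        Xa = Xw[:, self.add_idx]
        Aa = self.X[:, self.add_idx].T @ Xa
        beta_a = np.linalg.solve(Aa, Xa.T @ self.y)
        rss_a = float(w @ (self.y - self.X[:, self.add_idx] @ beta_a) ** 2)
        r2a = 1.0 - rss_a / tss
        p_a = self.add_idx.size
        r2a_adj = 1.0 - (1.0 - r2a) * (self.n - 1) / (self.n - p_a)
        return beta, np.sqrt(np.diag(cov)), r2_adj, r2a_adj

    def draw_weights(self, rng: np.random.Generator) -> np.ndarray:
        w = np.empty(self.n)
        for cell in self.cells:
            k = cell.size
            w[cell] = rng.multinomial(k, np.full(k, 1.0 / k))
        return w


def _ivw_terms(terms_f, beta_f, se_f, terms_m, beta_m, se_m):
    """IVW-combine per term over the union of sex-specific terms.

    A term estimated in one sex only passes through with full weight on that
    sex (the other cell was removed from the analysis).
    """
    fmap = {t: i for i, t in enumerate(terms_f)}
    mmap = {t: i for i, t in enumerate(terms_m)}
    all_terms = list(dict.fromkeys([*terms_f, *terms_m]))
    out = {}
    for t in all_terms:
        inf, inm = t in fmap, t in mmap
        if inf and inm:
            bf, vf = beta_f[fmap[t]], se_f[fmap[t]] ** 2
            bm, vm = beta_m[mmap[t]], se_m[mmap[t]] ** 2
            out[t] = ivw_combine(bf, vf, bm, vm) + (bf, bm)
        elif inf:
            bf, vf = beta_f[fmap[t]], se_f[fmap[t]] ** 2
            out[t] = (bf, vf, 1.0, bf, np.nan)
        else:
            bm, vm = beta_m[mmap[t]], se_m[mmap[t]] ** 2
            out[t] = (bm, vm, 0.0, np.nan, bm)
    return out


@dataclass
class BootstrapResult:
    effects: list[MetaEffect]
    shares: dict[str, HeritableShare]
    B: int
    seed: int | None

    def effects_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(e) for e in self.effects])

    def n_significant(self, term_class: str = "interaction",
                      alpha: float = 0.05) -> int:
        return sum(
            1 for e in self.effects
            if e.term_class == term_class and e.adj_p < alpha
        )


def bootstrap_inference(
    table: pd.DataFrame,
    trait: str,
    B: int = 10_000,
    seed: int | None = None,
    min_cell: int | None = 5,
    alpha: float = 0.05,
) -> BootstrapResult:
    """Studentized within-cell bootstrap of the IVW-combined coefficients.

    Each replicate resamples animals with replacement within every
    cross x sex cell (equivalently, multinomial case weights), refits both
    per-sex models, IVW-combines every coefficient, and studentizes against
    the replicate's own standard error: t* = (beta* - beta_hat) / SE*.
    Confidence intervals are percentile-t around the observed estimate; the
    raw p inverts the t* distribution; the maxT-adjusted p compares each
    observed |t| to the bootstrap maximum of |t*| over its family, separately
    for the main-effect and interaction families, with the
    (1 + count) / (B + 1) estimator.
    """
    if B < 100:
        warnings.warn(f"B = {B} bootstrap replicates is very small")
    data = {s: _SexData(table, s, trait, min_cell) for s in ("F", "M")}
    rng = np.random.default_rng(seed)

    obs_fit = {}
    for s, d in data.items():
        obs_fit[s] = d.fit_weighted(np.ones(d.n))
    combined = _ivw_terms(
        data["F"].columns, obs_fit["F"][0], obs_fit["F"][1],
        data["M"].columns, obs_fit["M"][0], obs_fit["M"][1],
    )
    terms = [t for t in combined if t != "Intercept"]
    classes = {}
    for t in terms:
        for d in data.values():
            if t in d.dm.term_classes:
                k = d.dm.term_classes[t]
                classes[t] = "main" if k.startswith("main") else k
                break
    est = np.array([combined[t][0] for t in terms])
    se = np.array([np.sqrt(combined[t][1]) for t in terms])
    t_obs = est / se

    tstar = np.empty((B, len(terms)))
    shares_star = {"F": np.empty(B), "M": np.empty(B)}
    for b in range(B):
        rep = {}
        for s, d in data.items():
            w = d.draw_weights(rng)
            beta, se_rep, r2f, r2a = d.fit_weighted(w)
            rep[s] = (beta, se_rep)
            shares_star[s][b] = (r2f - r2a) / r2f if r2f > 0 else np.nan
        comb = _ivw_terms(
            data["F"].columns, rep["F"][0], rep["F"][1],
            data["M"].columns, rep["M"][0], rep["M"][1],
        )
        for j, t in enumerate(terms):
            bstar, vstar = comb[t][0], comb[t][1]
            tstar[b, j] = (bstar - est[j]) / np.sqrt(vstar)

    effects = []
    fam_max = {}
    for fam in set(classes.values()):
        idx = [j for j, t in enumerate(terms) if classes[t] == fam]
        fam_max[fam] = np.max(np.abs(tstar[:, idx]), axis=1)
    for j, t in enumerate(terms):
        abs_t = abs(t_obs[j])
        raw_p = (1 + np.sum(np.abs(tstar[:, j]) >= abs_t)) / (B + 1)
        adj_p = (1 + np.sum(fam_max[classes[t]] >= abs_t)) / (B + 1)
        qlo, qhi = np.quantile(tstar[:, j], [alpha / 2, 1 - alpha / 2])
        effects.append(
            MetaEffect(
                term=t,
                term_class=classes[t],
                estimate=est[j],
                variance=se[j] ** 2,
                weight_f=combined[t][2],
                se=se[j],
                statistic=t_obs[j],
                raw_p=float(raw_p),
                adj_p=float(adj_p),
                ci_low=est[j] - qhi * se[j],
                ci_high=est[j] - qlo * se[j],
                beta_f=combined[t][3],
                beta_m=combined[t][4],
            )
        )

    shares = {}
    for s, d in data.items():
        _, _, r2f, r2a = obs_fit[s]
        prop = (r2f - r2a) / r2f if r2f > 0 else np.nan
        ss = shares_star[s]
        ss = ss[np.isfinite(ss)]
        lo, hi = (np.quantile(ss, [alpha / 2, 1 - alpha / 2])
                  if ss.size else (np.nan, np.nan))
        shares[s] = HeritableShare(
            sex=s, proportion=prop, r2_adj_full=r2f, r2_adj_additive=r2a,
            ci_low=float(lo), ci_high=float(hi), defined=r2f > 0,
        )
    return BootstrapResult(effects=effects, shares=shares, B=B, seed=seed)


# ---------------------------------------------------------------------------
# orchestration

@dataclass
class TraitAnalysis:
    trait: str
    winsorization: WinsorizeResult | None
    fits_full: dict
    fits_additive: dict
    joint: pd.DataFrame
    bootstrap: BootstrapResult | None
    shares: dict
    removed_cells: pd.DataFrame


def analyze_trait(
    table: pd.DataFrame,
    trait: str,
    winsorize_k: float | None = 4.0,
    B: int = 10_000,
    seed: int | None = 0,
    min_cell: int | None = 5,
    run_bootstrap: bool = True,
) -> TraitAnalysis:
    """End-to-end trait analysis.

    Winsorizes the pooled trait vector (both sexes, all crosses), removes
    small cross x sex cells, fits per-sex full and additive models, performs
    joint main-effect and interaction F-tests with Fisher cross-sex
    combination, runs the studentized maxT bootstrap, and computes the
    interaction share of heritable variation per sex.
    """
    work = table.copy()
    wres = None
    if winsorize_k is not None:
        wres = winsorize(pd.to_numeric(work[trait], errors="coerce"), winsorize_k)
        work[trait] = wres.values
    work_kept, removed = remove_small_cells(
        work[np.isfinite(pd.to_numeric(work[trait], errors="coerce"))],
        min_cell=min_cell or 0, by_sex=True,
    ) if min_cell else (work, pd.DataFrame())

    fits_full, fits_add, joint_rows = {}, {}, []
    for sex in ("F", "M"):
        ff = fit_sex_model(work_kept, sex, trait, True, min_cell=None)
        fa = fit_sex_model(work_kept, sex, trait, False, min_cell=None)
        fits_full[sex], fits_add[sex] = ff, fa
        for klass in ("main", "interaction"):
            F, df1, df2, p = joint_test(ff, klass)
            joint_rows.append((trait, sex, klass, F, df1, df2, p))
    joint = pd.DataFrame(
        joint_rows, columns=["trait", "sex", "term_class", "F", "df1", "df2", "p"]
    )
    meta_rows = []
    for klass in ("main", "interaction"):
        ps = joint.loc[joint["term_class"] == klass, "p"]
        meta_rows.append((trait, "meta", klass, np.nan, np.nan, np.nan,
                          fisher_combine(ps)))
    joint = pd.concat([joint, pd.DataFrame(meta_rows, columns=joint.columns)],
                      ignore_index=True)

    boot = None
    if run_bootstrap:
        boot = bootstrap_inference(work_kept, trait, B=B, seed=seed,
                                   min_cell=None)
        shares = boot.shares
    else:
        shares = {
            s: heritable_share(fits_full[s], fits_add[s]) for s in ("F", "M")
        }
    return TraitAnalysis(
        trait=trait,
        winsorization=wres,
        fits_full=fits_full,
        fits_additive=fits_add,
        joint=joint,
        bootstrap=boot,
        shares=shares,
        removed_cells=removed,
    )
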