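"""Per-gene partition of genetic variation into additive and interaction parts.

For each gene, SS_full is the sum of mean-centered squared fitted values of
the full interaction model (fitted on the expression scale with surrogate
covariates set to zero and a common reference library, so fitted values vary
between strains only), SS_additive the same for the model without interaction
terms, and the interaction share of genetic variation is
(SS_full - SS_additive) / SS_full, unclipped.  The share is only meaningful
for genes with evidence of genetic control (all-strain joint test, plain BH
across genes).  The estimator is biased upward by overfitting; the bias is
bounded by refitting both models to counts simulated from a Poisson around
the additive fit (no interactions by construction) and averaging the share
over replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionFits, GeneFit
from .glm import fit_nb_glm

__all__ = [
    "ExpressionVarShare",
    "interaction_variance_share",
    "variance_shares",
    "genetic_control_gate",
    "additive_null_bias",
    "summarize_shares",
]

log = logging.getLogger(__name__)


@dataclass
class ExpressionVarShare:
    gene: str
    ss_full: float
    ss_additive: float
    proportion: float
    defined: bool = True
    gate_p: float = np.nan
    gate_q: float = np.nan
    interaction_p: float = np.nan
    interaction_q: float = np.nan
    bias_mean: float = np.nan


def _genetic_fitted(params: pd.Series, X: pd.DataFrame) -> np.ndarray:
    """Fitted values from genetic terms only: exp(x_i . beta_genetic).

    Covariates are zeroed (their columns are simply absent from X here) and
    no library offset enters, so the fitted value is constant within a strain
    and the SS measures between-strain variation only.
    """
    cols = [c for c in X.columns if c in params.index]
    eta = X[cols].to_numpy(float) @ params[cols].to_numpy(float)
    return np.exp(eta)


def interaction_variance_share(
    fit: GeneFit,
    design_X: pd.DataFrame,
) -> ExpressionVarShare:
    """(SS_full - SS_additive) / SS_full from genetic fitted values.

    Undefined (flagged) when SS_full is zero: the full model fits no
    between-strain variation.
    """
    fv_full = _genetic_fitted(fit.params, design_X)
    fv_add = _genetic_fitted(fit.params_additive, design_X)
    ss_full = float(np.sum((fv_full - fv_full.mean()) ** 2))
    ss_add = float(np.sum((fv_add - fv_add.mean()) ** 2))
    if ss_full <= 0:
        return ExpressionVarShare(fit.gene, ss_full, ss_add, np.nan, defined=False)
    return ExpressionVarShare(
        fit.gene, ss_full, ss_add, (ss_full - ss_add) / ss_full
    )


def genetic_control_gate(
    fits: ExpressionFits,
    alpha: float = 0.05,
) -> tuple[list[str], pd.DataFrame]:
    """Genes with evidence of genetic control.

    Plain (unstratified) Benjamini-Hochberg across genes on the all-strain
    joint test p-values; genes with q < alpha pass the gate.
    """
    genes = fits.genes()
    if not genes:
        return [], pd.DataFrame(columns=["gene", "p", "q", "passed"])
    p = np.array([fits[g].tests["all_strain"][3] for g in genes])
    _, q, _, _ = multipletests(p, method="fdr_bh")
    table = pd.DataFrame({"gene": genes, "p": p, "q": q, "passed": q < alpha})
    return table.loc[table["passed"], "gene"].tolist(), table


def variance_shares(
    fits: ExpressionFits,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Interaction variance share for every fitted gene, with gate and
    interaction-test q-values attached."""
    X = fits.design.X
    _, gate = genetic_control_gate(fits, alpha)
    gate = gate.set_index("gene")
    pint = fits.p_frame("all_interaction")
    _, qint, _, _ = multipletests(pint.to_numpy(), method="fdr_bh")
    qint = pd.Series(qint, index=pint.index)
    rows = []
    for g in fits.genes():
        share = interaction_variance_share(fits[g], X)
        rows.append(
            {
                "gene": g,
                "ss_full": share.ss_full,
                "ss_additive": share.ss_additive,
                "proportion": share.proportion,
                "defined": share.defined,
                "gate_p": gate.loc[g, "p"],
                "gate_q": gate.loc[g, "q"],
                "gate_passed": bool(gate.loc[g, "passed"]),
                "interaction_p": pint[g],
                "interaction_q": qint[g],
            }
        )
    return pd.DataFrame(rows)


def additive_null_bias(
    fits: ExpressionFits,
    n_reps: int = 100,
    seed: int | None = 0,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Upper bound on the overfitting bias of the interaction share.

    For every gene, counts are simulated from a Poisson whose mean is the
    additive-model predicted mean (library offset and covariates included, so
    the simulated data look like the real data minus any interaction), both
    models are refit, and the share is recomputed.  The per-gene mean over
    ``n_reps`` replicates estimates the share that pure overfitting produces
    under exact additivity.  Returns per-gene mean proportions plus the
    cohort mean and quartiles as attributes of the frame (``.attrs``).
    """
    rng = np.random.default_rng(seed)
    gene_list = genes if genes is not None else fits.genes()
    dm = fits.design
    Xg = dm.X
    Xg_v = Xg.to_numpy(float)
    cov = fits.covariates
    if cov is not None:
        Xfull = np.hstack([Xg_v, cov.loc[Xg.index].to_numpy(float)])
        cols = list(Xg.columns) + list(cov.columns)
    else:
        Xfull = Xg_v
        cols = list(Xg.columns)
    int_idx = [cols.index(c) for c in dm.interaction_terms]
    add_cols = [j for j in range(len(cols)) if j not in int_idx]
    gen_cols_full = [cols.index(c) for c in Xg.columns]
    gen_cols_add = [j for j in add_cols if j in gen_cols_full]
    offset = fits.offset.to_numpy(float)

    # additive predicted means on the count scale, covariates as estimated
    results = {}
    for g in gene_list:
        fit = fits[g]
        mu_add = fit.fitted_additive.to_numpy(float)
        props = []
        for _ in range(n_reps):
            y = rng.poisson(mu_add).astype(float)
            ff = fit_nb_glm(y, Xfull, offset, dispersion=0.0)
            fa = fit_nb_glm(y, Xfull[:, add_cols], offset, dispersion=0.0)
            if not (ff.converged and fa.converged):
                log.warning("bias simulation: refit failed for %s, rep skipped", g)
                continue
            fv_full = np.exp(Xfull[:, gen_cols_full]
                             @ ff.beta[gen_cols_full])
            beta_a = pd.Series(fa.beta, index=[cols[j] for j in add_cols])
            fv_add = np.exp(
                Xfull[:, gen_cols_add]
                @ beta_a[[cols[j] for j in gen_cols_add]].to_numpy()
            )
            ssf = float(np.sum((fv_full - fv_full.mean()) ** 2))
            ssa = float(np.sum((fv_add - fv_add.mean()) ** 2))
            if ssf > 0:
                props.append((ssf - ssa) / ssf)
        results[g] = float(np.mean(props)) if props else np.nan

    frame = pd.DataFrame(
        {"gene": list(results), "bias_mean": list(results.values())}
    )
    vals = frame["bias_mean"].dropna().to_numpy()
    frame.attrs["cohort_mean"] = float(np.mean(vals)) if vals.size else np.nan
    if vals.size:
        q1, q3 = np.quantile(vals, [0.25, 0.75], method="median_unbiased")
        frame.attrs["q1"], frame.attrs["q3"] = float(q1), float(q3)
    return frame


def summarize_shares(
    shares: pd.DataFrame,
    alpha: float = 0.05,
    null_fdr: float = 0.5,
) -> pd.DataFrame:
    """Mean and quartiles of the interaction share per gene group.

    Groups: all gated genes; gated genes with a significant interaction
    (interaction q < alpha); gated genes with no evidence of interaction
    (interaction q > null_fdr).  Quartiles use the median-unbiased
    definition.  Empty groups are omitted.
    """
    gated = shares[shares["gate_passed"] & shares["defined"]]
    groups = {
        "all_gated": gated,
        "interaction_significant": gated[gated["interaction_q"] < alpha],
        "interaction_null": gated[gated["interaction_q"] > null_fdr],
    }
    rows = []
    for name, grp in groups.items():
        vals = grp["proportion"].dropna().to_numpy()
        if vals.size == 0:
            continue
        q1, q3 = np.quantile(vals, [0.25, 0.75], method="median_unbiased")
        rows.append((name, vals.size, float(np.mean(vals)), float(q1), float(q3)))
    return pd.DataFrame(rows, columns=["group", "n_genes", "mean", "q1", "q3"])
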