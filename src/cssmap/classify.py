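"""Classification of significant interactions as synergistic or antagonistic,
and the reversion-to-control test.

The additive prediction for a double-substitution cross is the sum of the two
single-substitution deviations on the model scale: linear for traits,
multiplicative for expression (log link).  An interaction is synergistic when
the observed double-cross value departs from control by more than the
additive prediction does, antagonistic when by less; exact ties are labelled
additive.  Antagonistic interactions typically revert the double cross to
control levels, which is tested by a model contrast (reverted iff p > 0.1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .expression import ExpressionFits, GeneFit

__all__ = [
    "InteractionClassification",
    "additive_prediction",
    "classify_interaction",
    "reversion_test",
    "reversion_test_groups",
    "classify_gene_interactions",
]


@dataclass
class InteractionClassification:
    id: str
    term: str
    mu_control: float
    mu_a: float
    mu_b: float
    mu_ab: float
    prediction: float
    klass: str
    reversion_p: float = np.nan
    reverted: bool = False


def additive_prediction(mu_control: float, mu_a: float, mu_b: float,
                        scale: str = "log") -> float:
    """Predicted double-substitution mean under no interaction.

    ``scale="linear"``: mu_a + mu_b - mu_control (trait scale).
    ``scale="log"``: mu_a * mu_b / mu_control -- additivity on the link scale
    of a log-link count model is multiplicative on the expression level.
    """
    if scale == "linear":
        return mu_a + mu_b - mu_control
    if scale == "log":
        if min(mu_control, mu_a, mu_b) <= 0:
            raise ValueError("log-scale prediction needs positive means")
        return mu_a * mu_b / mu_control
    raise ValueError(f"unknown scale {scale!r}")


def classify_interaction(mu_control: float, mu_a: float, mu_b: float,
                         mu_ab_observed: float, scale: str = "log") -> str:
    """Synergistic / antagonistic / additive relative to the additive prediction.

    Synergistic iff the observed double-cross value departs from control by
    more than the additive prediction does, antagonistic iff by less; exact
    equality is labelled additive.  Departure is measured on the model scale:
    absolute difference for ``scale="linear"``, absolute log-ratio for
    ``scale="log"`` (so the class depends only on the interaction
    coefficient relative to the main-effect sum).  Symmetric in the two
    single-substitution means.
    """
    pred = additive_prediction(mu_control, mu_a, mu_b, scale)
    if scale == "log":
        if mu_ab_observed <= 0:
            raise ValueError("log-scale classification needs positive means")
        d_obs = abs(np.log(mu_ab_observed / mu_control))
        d_pred = abs(np.log(pred / mu_control))
    else:
        d_obs = abs(mu_ab_observed - mu_control)
        d_pred = abs(pred - mu_control)
    if d_obs > d_pred:
        return "synergistic"
    if d_obs < d_pred:
        return "antagonistic"
    return "additive"


def reversion_test_groups(double_values, control_values) -> tuple[float, bool]:
    """Welch two-sample test of double-cross values against control values.

    Returns (p, reverted) with reverted iff p > 0.1: the double cross is
    statistically indistinguishable from control.
    """
    a = np.asarray(double_values, float)
    b = np.asarray(control_values, float)
    if a.size < 2 or b.size < 2:
        raise ValueError("reversion test needs >= 2 values per group")
    res = stats.ttest_ind(a, b, equal_var=False)
    p = float(res.pvalue)
    if not np.isfinite(p):  # zero within-group variance
        p = 1.0 if a.mean() == b.mean() else 0.0
    return p, p > 0.1


def reversion_test(fit: GeneFit, term: str) -> tuple[float, bool]:
    """Model-based contrast of the double cross against control for one gene.

    For interaction term int<m>:<p>, the log-scale contrast is
    beta_mat<m> + beta_pat<p> + beta_int -- the difference between the double
    cross and control linear predictors.  A moderated t (QL-scaled
    covariance, df_total) gives the two-sided p; reverted iff p > 0.1.
    """
    if not term.startswith("int"):
        raise ValueError(f"not an interaction term: {term!r}")
    m, p_ = term[3:].split(":")
    names = [f"mat{m}", f"pat{p_}", term]
    c = pd.Series(0.0, index=fit.params.index)
    for nm in names:
        c[nm] = 1.0
    est = float(c @ fit.params)
    var = float(c @ fit.cov @ c)
    if var <= 0 or not np.isfinite(var):
        raise ValueError("degenerate contrast variance")
    t = est / np.sqrt(var)
    p = 2.0 * float(stats.t.sf(abs(t), fit.df_total))
    return p, p > 0.1


def fitted_group_means(fit: GeneFit, term: str) -> tuple[float, float, float, float]:
    """Model-fitted control / single / single / double means, covariates zeroed.

    Expression scale (exp of the genetic linear predictor at the reference
    library); consistent with classification being applied to
    model-significant interactions rather than raw group averages.
    """
    m, p_ = term[3:].split(":")
    b = fit.params
    mu0 = float(np.exp(b["Intercept"]))
    mu_a = float(np.exp(b["Intercept"] + b[f"mat{m}"]))
    mu_b = float(np.exp(b["Intercept"] + b[f"pat{p_}"]))
    mu_ab = float(np.exp(b["Intercept"] + b[f"mat{m}"] + b[f"pat{p_}"] + b[term]))
    return mu0, mu_a, mu_b, mu_ab


def classify_gene_interactions(
    fits: ExpressionFits,
    calls: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Classify every significant ieQTL call and test reversion to control.

    Returns one row per significant interaction call with fitted means,
    additive prediction, class and the reversion p-value.
    """
    sig = calls[(calls["kind"] == "ieQTL") & (calls["q"] < alpha)]
    rows = []
    for gene, term in sig[["gene", "term"]].itertuples(index=False):
        fit = fits[gene]
        mu0, mu_a, mu_b, mu_ab = fitted_group_means(fit, term)
        pred = additive_prediction(mu0, mu_a, mu_b, "log")
        klass = classify_interaction(mu0, mu_a, mu_b, mu_ab, "log")
        rp, rev = reversion_test(fit, term)
        rows.append((gene, term, mu0, mu_a, mu_b, mu_ab, pred, klass, rp, rev))
    return pd.DataFrame(
        rows,
        columns=[
            "gene", "term", "mu_control", "mu_a", "mu_b", "mu_double",
            "prediction", "class", "reversion_p", "reverted",
        ],
    )
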