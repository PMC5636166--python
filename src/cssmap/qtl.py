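"""Expression QTL calls from per-gene tests, with cis/trans labels and
stratified false-discovery control.

Main-effect expression QTLs (meQTLs: one substituted chromosome's term) and
interaction expression QTLs (ieQTLs: one chromosome pair's term) are called
from the moderated per-term tests.  A call is cis when the regulated gene
lies on a substituted chromosome of the term (either of the two for a pair),
trans otherwise.  Benjamini-Hochberg is applied independently within each
stratum -- (term chromosome(s)) x (cis/trans) -- which is more powerful when
true-signal density differs by stratum.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .expression import ExpressionFits
from .simulate import ExprDataset

__all__ = [
    "term_chromosomes",
    "classify_locality",
    "stratified_bh",
    "call_qtls",
    "significant_calls",
    "summarize_calls",
]


def term_chromosomes(term: str) -> tuple[str, ...]:
    """Chromosome id(s) addressed by a design term name."""
    if term.startswith("int"):
        return tuple(term[3:].split(":"))
    if term.startswith(("mat", "pat")):
        return (term[3:],)
    raise ValueError(f"not a genetic term: {term!r}")


def classify_locality(gene_chrom, term_chroms) -> str:
    """'cis' iff the gene's chromosome is among the term's chromosome(s)."""
    if gene_chrom is None or (isinstance(gene_chrom, float) and np.isnan(gene_chrom)):
        raise ValueError("gene chromosome unknown")
    g = str(gene_chrom).strip()
    if not g or g.lower() in {"nan", "none", "na"}:
        raise ValueError("gene chromosome unknown")
    chroms = {str(c) for c in (
        term_chroms if isinstance(term_chroms, (tuple, list, set, frozenset))
        else (term_chroms,)
    )}
    return "cis" if g in chroms else "trans"


def stratified_bh(
    table: pd.DataFrame,
    alpha: float = 0.05,
    p_col: str = "p",
    stratum_col: str = "stratum",
) -> pd.DataFrame:
    """Benjamini-Hochberg within each stratum independently.

    Adds ``q`` and ``significant`` columns; empty strata are skipped.  With a
    single stratum this reduces to plain BH.
    """
    p = table[p_col].to_numpy(float)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    out = table.copy()
    out["q"] = np.nan
    for _, idx in out.groupby(stratum_col, sort=False).groups.items():
        pv = out.loc[idx, p_col].to_numpy(float)
        if pv.size == 0:
            continue
        _, q, _, _ = multipletests(pv, method="fdr_bh")
        out.loc[idx, "q"] = q
    out["significant"] = out["q"] < alpha
    return out


def call_qtls(
    fits: ExpressionFits,
    gene_chrom: pd.Series,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Turn per-gene per-term tests into meQTL/ieQTL calls.

    Returns one row per gene x genetic term with columns gene, term, kind
    (meQTL for main terms, ieQTL for interaction terms), locality, stratum,
    p, effect (log fold change / interaction coefficient), q and significant.
    meQTL strata are (chromosome, locality); ieQTL strata are (chromosome
    pair, locality).  FDR is controlled within each stratum at ``alpha``.
    """
    rows = []
    main_terms = fits.design.main_terms
    int_terms = fits.design.interaction_terms
    for g, fit in fits.fits.items():
        gchrom = gene_chrom.loc[g]
        for term in (*main_terms, *int_terms):
            if term not in fit.tests:
                continue
            chroms = term_chromosomes(term)
            loc = classify_locality(gchrom, chroms)
            kind = "ieQTL" if term.startswith("int") else "meQTL"
            rows.append(
                (
                    g,
                    term,
                    kind,
                    loc,
                    f"{'-'.join(chroms)}:{loc}",
                    fit.tests[term][3],
                    float(fit.params[term]),
                )
            )
    calls = pd.DataFrame(
        rows, columns=["gene", "term", "kind", "locality", "stratum", "p", "effect"]
    )
    calls = stratified_bh(calls, alpha=alpha)
    # deterministic output order; ties in q broken by gene id
    calls = calls.sort_values(["kind", "term", "q", "gene"],
                              kind="mergesort").reset_index(drop=True)
    return calls


def significant_calls(calls: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    return calls[calls["q"] < alpha].reset_index(drop=True)


def summarize_calls(
    calls: pd.DataFrame,
    dataset: ExprDataset,
    alpha: float = 0.05,
) -> dict:
    """Summaries of the QTL landscape.

    Returns a dict with:

    - ``per_term``: per term (strain or cross), the number and percentage of
      expressed genes with a cis call (denominator: expressed genes on the
      substituted chromosome(s)) and with a trans call (denominator: the
      remaining expressed genes), plus the denominators.
    - ``per_gene``: number of distinct QTL calls per gene (significant only),
      split by kind.
    - ``multi_qtl``: fraction of called genes carrying more than one call,
      per kind.
    - ``cis_trans_spearman``: Spearman correlation between the cis and trans
      percentage vectors across terms, per kind.
    """
    sig = significant_calls(calls, alpha)
    gene_chrom = dataset.gene_chrom
    n_expressed = len(gene_chrom)

    rows = []
    for (term, kind), grp in sig.groupby(["term", "kind"], sort=False):
        chroms = set(term_chromosomes(term))
        on = gene_chrom.isin(chroms)
        denom_cis = int(on.sum())
        denom_trans = n_expressed - denom_cis
        n_cis = grp.loc[grp["locality"] == "cis", "gene"].nunique()
        n_trans = grp.loc[grp["locality"] == "trans", "gene"].nunique()
        rows.append(
            (
                term, kind,
                n_cis, denom_cis,
                100.0 * n_cis / denom_cis if denom_cis else np.nan,
                n_trans, denom_trans,
                100.0 * n_trans / denom_trans if denom_trans else np.nan,
            )
        )
    # include tested terms with zero significant calls
    tested_terms = calls[["term", "kind"]].drop_duplicates()
    have = {(r[0], r[1]) for r in rows}
    for term, kind in tested_terms.itertuples(index=False):
        if (term, kind) in have:
            continue
        chroms = set(term_chromosomes(term))
        denom_cis = int(gene_chrom.isin(chroms).sum())
        rows.append((term, kind, 0, denom_cis,
                     0.0 if denom_cis else np.nan,
                     0, n_expressed - denom_cis,
                     0.0 if n_expressed - denom_cis else np.nan))
    per_term = pd.DataFrame(
        rows,
        columns=[
            "term", "kind", "n_cis", "genes_on_chrom", "pct_cis",
            "n_trans", "genes_elsewhere", "pct_trans",
        ],
    ).sort_values(["kind", "term"], kind="mergesort").reset_index(drop=True)

    per_gene = (
        sig.groupby(["gene", "kind"]).size().rename("n_qtls").reset_index()
    )
    multi = {}
    for kind, grp in per_gene.groupby("kind"):
        multi[kind] = float((grp["n_qtls"] > 1).mean()) if len(grp) else np.nan

    spearman = {}
    for kind, grp in per_term.groupby("kind"):
        ok = grp[["pct_cis", "pct_trans"]].dropna()
        if len(ok) >= 3:
            spearman[kind] = float(
                sps.spearmanr(ok["pct_cis"], ok["pct_trans"]).statistic
            )
        else:
            spearman[kind] = np.nan

    return {
        "per_term": per_term,
        "per_gene": per_gene,
        "multi_qtl": multi,
        "cis_trans_spearman": spearman,
    }
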