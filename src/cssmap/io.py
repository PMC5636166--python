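"""File formats, run configuration and end-to-end orchestration.

Phenotype tables are CSV (animal_id, sex, maternal_sub, paternal_sub,
body_weight_g, glucose_mg_dl; empty substitution = control).  Count matrices
are TSV (gene_id + one column per sample) or MatrixMarket with ``.rows`` /
``.cols`` sidecar name files; gene->chromosome maps are BED (chrom, start,
end, gene_id; 0-based half-open, only the chromosome is used) or two-column
TSV.  Chromosome labels are opaque strings; a leading ``chr`` prefix is
stripped.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd

from .design import CrossLabel
from .simulate import ExprDataset

__all__ = [
    "read_pheno",
    "read_counts",
    "read_gene_map",
    "RunConfig",
    "run_pipeline",
]

log = logging.getLogger(__name__)

PHENO_COLUMNS = ["animal_id", "sex", "maternal_sub", "paternal_sub"]
TRAIT_COLUMNS = ["body_weight_g", "glucose_mg_dl"]


def _norm_chrom(c) -> str | None:
    if c is None or (isinstance(c, float) and np.isnan(c)):
        return None
    s = str(c).strip()
    if s.lower().startswith("chr"):
        s = s[3:]
    if s == "" or s.lower() in {"nan", "none", "na"}:
        return None
    if s.endswith(".0") and s[:-2].isdigit():
        s = s[:-2]
    return s


def read_pheno(
    path,
    maternal_panel=None,
    paternal_panel=None,
) -> pd.DataFrame:
    """Read a per-animal phenotype CSV.

    Empty substitution fields denote the control cross.  Trait values of
    ``NA`` are retained as missing (the animal is excluded from that trait's
    fit only).  Missing required columns, non-numeric trait values and
    substitutions outside a given panel raise with the offending row number.
    """
    table = pd.read_csv(path, dtype={"maternal_sub": str, "paternal_sub": str})
    missing = [c for c in PHENO_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    traits = [c for c in TRAIT_COLUMNS if c in table.columns]
    if not traits:
        raise ValueError(f"{path}: no trait columns found (expected one of "
                         f"{TRAIT_COLUMNS})")
    for col in ("maternal_sub", "paternal_sub"):
        table[col] = [_norm_chrom(v) for v in table[col]]
    for trait in traits:
        vals = pd.to_numeric(table[trait], errors="coerce")
        bad = table.index[table[trait].notna()
                          & table[trait].astype(str).str.strip().ne("")
                          & ~table[trait].astype(str).str.upper().eq("NA")
                          & vals.isna()]
        if len(bad):
            raise ValueError(
                f"{path}: non-numeric {trait} value at row {bad[0] + 2}"
            )
        table[trait] = vals
    bad_sex = table.index[~table["sex"].isin(["F", "M"])]
    if len(bad_sex):
        raise ValueError(f"{path}: invalid sex at row {bad_sex[0] + 2}")
    for side, panel in (("maternal_sub", maternal_panel),
                        ("paternal_sub", paternal_panel)):
        if panel is None:
            continue
        allowed = {_norm_chrom(c) for c in panel}
        bad = table.index[~table[side].isin(allowed) & table[side].notna()]
        if len(bad):
            raise ValueError(
                f"{path}: unknown {side} chromosome "
                f"{table.loc[bad[0], side]!r} at row {bad[0] + 2}"
            )
    return table


def read_gene_map(path) -> pd.Series:
    """Gene -> chromosome map from BED (4+ columns) or two-column TSV."""
    probe = pd.read_csv(path, sep="\t", header=None, nrows=5, dtype=str)
    if probe.shape[1] >= 4 and probe.iloc[:, 1].str.isdigit().all():
        bed = pd.read_csv(path, sep="\t", header=None, dtype=str)
        genes = bed.iloc[:, 3]
        chroms = bed.iloc[:, 0]
    else:
        two = pd.read_csv(path, sep="\t", header=None, dtype=str)
        if two.shape[1] < 2:
            raise ValueError(f"{path}: need BED or two-column gene->chrom TSV")
        genes, chroms = two.iloc[:, 0], two.iloc[:, 1]
    if genes.duplicated().any():
        dup = genes[genes.duplicated()].iloc[0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    return pd.Series(
        [_norm_chrom(c) for c in chroms], index=pd.Index(genes, name="gene_id"),
        name="chrom",
    )


def read_counts(path, samples_path, genes_path) -> ExprDataset:
    """Assemble an ExprDataset from counts + sample sheet + gene map files."""
    path = Path(path)
    if path.suffix == ".mtx":
        from scipy.io import mmread

        mat = np.asarray(mmread(path).todense() if hasattr(mmread(path), "todense")
                         else mmread(path))
        rows = Path(str(path) + ".rows").read_text().split()
        cols = Path(str(path) + ".cols").read_text().split()
        counts = pd.DataFrame(np.asarray(mat, dtype=np.int64),
                              index=pd.Index(rows, name="gene_id"),
                              columns=cols)
    else:
        counts = pd.read_csv(path, sep="\t", index_col=0)
        counts.index.name = "gene_id"
    if counts.index.duplicated().any():
        dup = counts.index[counts.index.duplicated()][0]
        raise ValueError(f"{path}: duplicated gene id {dup!r}")
    samples = pd.read_csv(samples_path, sep="\t", index_col=0,
                          dtype={"maternal_sub": str, "paternal_sub": str})
    for col in ("maternal_sub", "paternal_sub"):
        if col not in samples.columns:
            raise ValueError(f"{samples_path}: missing column {col}")
        samples[col] = [_norm_chrom(v) for v in samples[col]]
    unknown = set(counts.columns) - set(samples.index.astype(str))
    if unknown:
        raise ValueError(
            f"samples in counts absent from sample sheet: {sorted(unknown)[:5]}"
        )
    gene_chrom = read_gene_map(genes_path)
    missing = set(counts.index) - set(gene_chrom.index)
    if missing:
        raise ValueError(
            f"genes without chromosome annotation: {sorted(missing)[:5]}"
        )
    return ExprDataset(
        counts=counts.astype(np.int64),
        samples=samples.loc[list(counts.columns)],
        gene_chrom=gene_chrom,
    )


@dataclass
class RunConfig:
    """End-to-end run configuration; every threshold is echoed to provenance."""

    pheno_path: str | None = None
    counts_path: str | None = None
    samples_path: str | None = None
    genes_path: str | None = None
    simulate_profile: str | None = None
    traits: tuple = ("glucose_mg_dl", "body_weight_g")
    winsorize_k: float = 4.0
    winsorize_traits: tuple = ("glucose_mg_dl",)
    min_cell: int = 5
    bootstrap_reps: int = 10_000
    n_surrogates: int = 5
    filter_min_count: int = 15
    filter_min_frac: float = 0.75
    qc_n_mads: float = 5.0
    fdr_alpha: float = 0.05
    reversion_threshold: float = 0.1
    bias_reps: int = 100
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("traits", "winsorize_traits"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def substream(self, name: str) -> int:
        """Named, reproducible child seed (kept below 2**31)."""
        import zlib

        ss = np.random.SeedSequence([self.seed, zlib.crc32(name.encode())])
        return int(ss.generate_state(1)[0] % (2**31))


def _write_tsv(frame: pd.DataFrame, path: Path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.8g")


def run_pipeline(config: RunConfig, out_dir) -> Path:
    """Run the phenotype and/or expression pipelines and write a report directory.

    Writes per-stage TSVs, a provenance JSON (full config, seeds, stage
    record counts) and a human-readable summary.  Any stage error aborts with
    the stage named.
    """
    from . import classify as _classify
    from . import expression as _expr
    from . import pheno as _pheno
    from . import qtl as _qtl
    from . import simulate as _sim
    from . import varpart as _vp

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    provenance: dict = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                                   for k, v in asdict(config).items()},
                        "stages": {}}
    summary_lines: list[str] = []
    t0 = time.time()

    def stage(name):
        log.info("stage %s starting (t=%.1fs)", name, time.time() - t0)
        return name

    try:
        if config.simulate_profile:
            name = stage("simulate")
            paths = _sim.make_fixture(config.simulate_profile, out / "fixture",
                                      seed=config.substream("fixture"))
            config.pheno_path = str(paths["pheno"])
            config.counts_path = str(paths["counts"])
            config.samples_path = str(paths["samples"])
            config.genes_path = str(paths["genes"])
            provenance["stages"][name] = {"profile": config.simulate_profile}

        if config.pheno_path:
            name = stage("pheno")
            table = read_pheno(config.pheno_path)
            provenance["stages"][name] = {"n_animals": len(table)}
            for trait in config.traits:
                if trait not in table.columns:
                    continue
                k = config.winsorize_k if trait in config.winsorize_traits else None
                res = _pheno.analyze_trait(
                    table, trait,
                    winsorize_k=k,
                    B=config.bootstrap_reps,
                    seed=config.substream(f"pheno-bootstrap-{trait}"),
                    min_cell=config.min_cell,
                )
                eff = res.bootstrap.effects_frame()
                # attach average (additive-model) effects for comparison
                avg = {}
                for s in ("F", "M"):
                    fa = res.fits_additive[s]
                    for t, v in fa.params.items():
                        avg.setdefault(t, {})[s] = (v, fa.bse[t] ** 2)
                avg_est = []
                for t in eff["term"]:
                    d = avg.get(t, {})
                    if len(d) == 2:
                        avg_est.append(_pheno.ivw_combine(
                            d["F"][0], d["F"][1], d["M"][0], d["M"][1])[0])
                    elif d:
                        avg_est.append(next(iter(d.values()))[0])
                    else:
                        avg_est.append(np.nan)
                eff.insert(3, "average_estimate", avg_est)
                _write_tsv(eff, out / f"effects_{trait}.tsv")
                _write_tsv(res.joint, out / f"joint_tests_{trait}.tsv")
                share_rows = [
                    {"sex": s, **{k: v for k, v in vars(h).items() if k != "sex"}}
                    for s, h in res.shares.items()
                ]
                _write_tsv(pd.DataFrame(share_rows), out / f"share_{trait}.tsv")
                if len(res.removed_cells):
                    rc = res.removed_cells.copy()
                    rc["cross"] = rc["cross"].map(str)
                    _write_tsv(rc, out / f"removed_cells_{trait}.tsv")
                stage_info = {
                    "n_significant_interactions":
                        res.bootstrap.n_significant("interaction",
                                                    config.fdr_alpha),
                    "removed_cells": len(res.removed_cells),
                }
                if res.winsorization:
                    stage_info["winsorize_ceiling"] = res.winsorization.ceiling
                    stage_info["winsorize_n_modified"] = res.winsorization.n_modified
                provenance["stages"][f"pheno:{trait}"] = stage_info
                summary_lines.append(
                    f"{trait}: {stage_info['n_significant_interactions']} "
                    f"significant interaction crosses (maxT adj p < "
                    f"{config.fdr_alpha}); interaction share of heritable "
                    "variation "
                    + ", ".join(
                        f"{s}={h.proportion:.2f}" for s, h in res.shares.items()
                        if np.isfinite(h.proportion)
                    )
                )

        if config.counts_path:
            name = stage("expression")
            ds = read_counts(config.counts_path, config.samples_path,
                             config.genes_path)
            ds, flagged = _expr.qc_samples(ds, n_mads=config.qc_n_mads)
            ds = _expr.filter_genes(ds, config.filter_min_count,
                                    config.filter_min_frac)
            dm = _expr.build_design_matrix(ds.samples)
            sv = _expr.estimate_surrogates(ds, dm, k=config.n_surrogates)
            fits = _expr.fit_expression_models(ds, covariates=sv)
            provenance["stages"][name] = {
                "flagged_samples": flagged,
                "n_samples": ds.n_samples,
                "n_genes_expressed": ds.n_genes,
                "n_genes_fit": len(fits.fits),
                "n_failed": len(fits.failed),
            }

            name = stage("qtl_calls")
            calls = _qtl.call_qtls(fits, ds.gene_chrom, alpha=config.fdr_alpha)
            _write_tsv(calls, out / "qtl_calls.tsv")
            summ = _qtl.summarize_calls(calls, ds, alpha=config.fdr_alpha)
            _write_tsv(summ["per_term"], out / "qtl_summary.tsv")
            provenance["stages"][name] = {
                "n_meqtl": int(((calls["kind"] == "meQTL")
                                & calls["significant"]).sum()),
                "n_ieqtl": int(((calls["kind"] == "ieQTL")
                                & calls["significant"]).sum()),
            }

            name = stage("classification")
            klass = _classify.classify_gene_interactions(fits, calls,
                                                         config.fdr_alpha)
            _write_tsv(klass, out / "interaction_classes.tsv")
            n_ant = int((klass["class"] == "antagonistic").sum())
            n_syn = int((klass["class"] == "synergistic").sum())
            provenance["stages"][name] = {
                "antagonistic": n_ant, "synergistic": n_syn,
                "reverted_frac": float(klass["reverted"].mean())
                if len(klass) else np.nan,
            }
            if n_ant + n_syn:
                summary_lines.append(
                    f"expression: {n_ant + n_syn} classified interactions, "
                    f"{100 * n_ant / (n_ant + n_syn):.0f}% antagonistic"
                )

            name = stage("varpart")
            shares = _vp.variance_shares(fits, alpha=config.fdr_alpha)
            _write_tsv(shares, out / "variance_shares.tsv")
            groups = _vp.summarize_shares(shares, alpha=config.fdr_alpha)
            _write_tsv(groups, out / "variance_share_groups.tsv")
            provenance["stages"][name] = {
                "groups": groups.to_dict("records"),
            }
            for rec in groups.to_dict("records"):
                summary_lines.append(
                    f"interaction share [{rec['group']}]: mean "
                    f"{rec['mean']:.2f} (Q1 {rec['q1']:.2f}, Q3 {rec['q3']:.2f},"
                    f" n={rec['n_genes']})"
                )
    except Exception as exc:  # noqa: BLE001 - abort with stage name
        raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc

    provenance["runtime_s"] = round(time.time() - t0, 2)
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2,
                                                    default=str))
    (out / "summary.txt").write_text("\n".join(summary_lines) + "\n")
    return out
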