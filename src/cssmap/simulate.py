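"""Synthetic CSS-cross phenotype tables and RNA-seq count matrices with ground truth.

The generators emulate the statistical structure the analysis assumes: an
unbalanced panel of control / single / double chromosome-substitution crosses,
sex-specific main and interaction effects with heteroscedastic Normal noise on
traits, and negative-binomial gene counts with library-size variation, latent
batch factors, cis-enriched main effects and mostly antagonistic interaction
effects on the log scale.  Every nonzero simulated effect is recorded in a
truth table so recovery can be tested end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .design import (
    MATERNAL_PANEL,
    PATERNAL_PANEL,
    CrossLabel,
    build_design_matrix,
    enumerate_crosses,
)

__all__ = [
    "PhenoSimConfig",
    "ExprSimConfig",
    "ExprDataset",
    "simulate_phenotypes",
    "simulate_counts",
    "make_fixture",
]

TRAITS = ("body_weight_g", "glucose_mg_dl")

# mouse autosome lengths (Mb, rounded) used to apportion genes to chromosomes
MOUSE_CHROM_MB = {
    "1": 195, "2": 182, "3": 160, "4": 157, "5": 152, "6": 150, "7": 145,
    "8": 130, "9": 124, "10": 131, "11": 122, "12": 120, "13": 120,
    "14": 125, "15": 104, "16": 98, "17": 95, "18": 91, "19": 61,
}


@dataclass
class PhenoSimConfig:
    """Configuration for the phenotype generator.

    Defaults emulate the published study conditions: fasting glucose baseline
    near 110 mg/dL and body weight near 17 g at 5 weeks, per-sex residual
    noise (glucose SD ~15 mg/dL, weight SD ~1.5 g), 10-30 animals per
    cross x sex cell with larger control groups, and a low rate of large
    positive glucose outliers (above the mean only, so a winsorization
    ceiling can remove them).
    """

    maternal_panel: tuple = MATERNAL_PANEL
    paternal_panel: tuple = PATERNAL_PANEL
    exclusions: tuple = (CrossLabel("3", "4"),)
    #: (n_control, n_single, n_double) animals per sex per cell; a dict
    #: {(CrossLabel, sex): n} may be given instead for full control.
    cell_sizes: tuple | dict = (40, 15, 14)
    baselines: dict = field(
        default_factory=lambda: {
            "F": {"body_weight_g": 16.0, "glucose_mg_dl": 108.0},
            "M": {"body_weight_g": 18.0, "glucose_mg_dl": 112.0},
        }
    )
    #: trait -> sex -> {chrom: effect}; maternal/paternal side inferred from panel
    main_effects: dict = field(default_factory=dict)
    #: trait -> sex -> {(mat, pat): effect}
    interaction_effects: dict = field(default_factory=dict)
    residual_sd: dict = field(
        default_factory=lambda: {
            "F": {"body_weight_g": 1.4, "glucose_mg_dl": 16.0},
            "M": {"body_weight_g": 1.6, "glucose_mg_dl": 14.0},
        }
    )
    outlier_rate: float = 0.007
    outlier_magnitude: float = 120.0
    outlier_traits: tuple = ("glucose_mg_dl",)
    seed: int = 0

    def __post_init__(self):
        for sex, d in self.residual_sd.items():
            for t, sd in d.items():
                if sd <= 0:
                    raise ValueError(f"residual SD must be > 0 ({sex}/{t})")
        if not 0 <= self.outlier_rate <= 1:
            raise ValueError("outlier_rate must lie in [0, 1]")

    @classmethod
    def paper_like(cls, seed: int = 0) -> "PhenoSimConfig":
        """Glucose architecture resembling the published panel.

        Five antagonistic glucose interactions whose main effects raise
        glucose by 12-25 mg/dL and cancel in the double cross; two modest
        body-weight main effects and no weight interactions.
        """
        glu_m = {"3": 25.0, "5": 15.6, "4": 17.5}
        glu_f = {"3": 22.0, "5": 18.0, "4": 16.0}
        # antagonistic cancellation: interaction = -(main_m + main_p)
        pairs = [("3", "5"), ("3", "4"), ("6", "5"), ("14", "4"), ("17", "5")]
        ints_m = {}
        ints_f = {}
        for m, p in pairs:
            ints_m[(m, p)] = -(glu_m.get(m, 0.0) + glu_m.get(p, 0.0))
            ints_f[(m, p)] = -(glu_f.get(m, 0.0) + glu_f.get(p, 0.0))
        return cls(
            exclusions=(),
            main_effects={
                "glucose_mg_dl": {"M": dict(glu_m), "F": dict(glu_f)},
                "body_weight_g": {
                    "M": {"8": 1.23, "17": -1.13},
                    "F": {"8": 1.0, "17": -1.0},
                },
            },
            interaction_effects={"glucose_mg_dl": {"M": ints_m, "F": ints_f}},
            seed=seed,
        )


def _cell_size(config: PhenoSimConfig, cross: CrossLabel, sex: str) -> int:
    if isinstance(config.cell_sizes, dict):
        return int(config.cell_sizes.get((cross, sex), 0))
    n_ctrl, n_single, n_double = config.cell_sizes
    return int((n_ctrl, n_single, n_double)[cross.n_substitutions])


def simulate_phenotypes(
    config: PhenoSimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a per-animal phenotype table and its ground-truth effect table.

    Trait value = sex baseline + maternal main + paternal main + interaction
    + Normal(0, SD_sex); with probability ``outlier_rate`` a positive outlier
    of ``outlier_magnitude`` is added (outlier traits only).  Fully
    deterministic under ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    crosses = enumerate_crosses(
        config.maternal_panel, config.paternal_panel, config.exclusions
    )
    rows = []
    for cross in crosses:
        for sex in ("F", "M"):
            n = _cell_size(config, cross, sex)
            for _ in range(n):
                rows.append((sex, cross.maternal_sub, cross.paternal_sub))
    if not rows:
        raise ValueError("empty design: no animals to simulate")
    table = pd.DataFrame(rows, columns=["sex", "maternal_sub", "paternal_sub"])
    table.insert(0, "animal_id", [f"A{i:04d}" for i in range(len(table))])

    truth_rows = []
    for trait in TRAITS:
        values = np.empty(len(table))
        for sex in ("F", "M"):
            idx = np.flatnonzero((table["sex"] == sex).to_numpy())
            base = config.baselines[sex][trait]
            mains = config.main_effects.get(trait, {}).get(sex, {})
            ints = config.interaction_effects.get(trait, {}).get(sex, {})
            sd = config.residual_sd[sex][trait]
            mu = np.full(idx.size, float(base))
            mat = table["maternal_sub"].to_numpy(object)[idx]
            pat = table["paternal_sub"].to_numpy(object)[idx]
            for chrom, eff in mains.items():
                mu += np.where((mat == str(chrom)) | (pat == str(chrom)), eff, 0.0)
            for (m, p), eff in ints.items():
                mu += np.where((mat == str(m)) & (pat == str(p)), eff, 0.0)
            values[idx] = mu + rng.normal(0.0, sd, idx.size)
            for chrom, eff in mains.items():
                if eff != 0:
                    side = "mat" if str(chrom) in config.maternal_panel else "pat"
                    truth_rows.append(
                        (trait, sex, f"{side}{chrom}", float(eff), "main")
                    )
            for (m, p), eff in ints.items():
                if eff != 0:
                    a = mains.get(m, 0.0)
                    b = mains.get(p, 0.0)
                    klass = (
                        "interaction-antagonistic"
                        if abs(a + b + eff) < abs(a + b)
                        else "interaction-synergistic"
                    )
                    truth_rows.append((trait, sex, f"int{m}:{p}", float(eff), klass))
        if trait in config.outlier_traits and config.outlier_rate > 0:
            hit = rng.random(len(table)) < config.outlier_rate
            values = values + np.where(hit, config.outlier_magnitude, 0.0)
        table[trait] = values

    truth = pd.DataFrame(
        truth_rows, columns=["trait", "sex", "term", "coefficient", "class"]
    )
    return table, truth


@dataclass
class ExprDataset:
    """Gene-level count matrix with sample sheet and gene->chromosome map.

    ``counts`` is genes x samples (non-negative integers); ``samples`` is
    indexed by sample id with ``maternal_sub``/``paternal_sub`` columns;
    ``gene_chrom`` maps gene id -> chromosome label.
    """

    counts: pd.DataFrame
    samples: pd.DataFrame
    gene_chrom: pd.Series
    lib_sizes: pd.Series | None = None

    def __post_init__(self):
        if list(self.counts.columns) != list(self.samples.index):
            if set(self.counts.columns) != set(self.samples.index):
                raise ValueError("counts columns and sample sheet do not match")
            self.samples = self.samples.loc[self.counts.columns]
        missing = set(self.counts.index) - set(self.gene_chrom.index)
        if missing:
            raise ValueError(f"{len(missing)} genes lack a chromosome annotation")
        self.gene_chrom = self.gene_chrom.loc[self.counts.index].astype(str)
        if self.lib_sizes is None:
            self.lib_sizes = self.counts.sum(axis=0).astype(float)
        else:
            self.lib_sizes = self.lib_sizes.loc[self.counts.columns].astype(float)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def subset_genes(self, genes) -> "ExprDataset":
        return ExprDataset(
            counts=self.counts.loc[genes],
            samples=self.samples,
            gene_chrom=self.gene_chrom.loc[genes],
            lib_sizes=self.lib_sizes,
        )

    def subset_samples(self, samples) -> "ExprDataset":
        return ExprDataset(
            counts=self.counts[samples],
            samples=self.samples.loc[samples],
            gene_chrom=self.gene_chrom,
            lib_sizes=self.lib_sizes.loc[samples],
        )


@dataclass
class ExprSimConfig:
    """Configuration for the count-matrix generator.

    Defaults emulate the published expression design: males only, replicate
    counts 20 (control) / 8 (single CSS) / 5 (double CSS), one excluded
    double cross, negative-binomial counts with a mean-dispersion trend,
    lognormal library sizes, a couple of latent batch factors, cis-enriched
    main effects and interaction effects that are 96% antagonistic
    (constructed as exact cancellation on the log scale by default).
    """

    n_genes: int = 2000
    maternal_panel: tuple = MATERNAL_PANEL
    paternal_panel: tuple = PATERNAL_PANEL
    exclusions: tuple = (CrossLabel("3", "4"),)
    replicates: tuple = (20, 8, 5)  # control / single / double
    chrom_sizes: dict = field(default_factory=lambda: dict(MOUSE_CHROM_MB))
    baseline_log_mean: tuple = (5.0, 1.2)  # Normal(mean, sd) of log count at ref lib
    dispersion: tuple = (0.05, 0.35)  # lognormal(median, sd of log10) of NB phi
    dispersion_trend_scale: float = 1.0  # multiply trend 1/mu component
    lib_size_log10_sd: float = 0.12
    mean_lib_size: float = 3.0e6
    n_batch: int = 2
    batch_loading_scale: float = 0.25
    batch_loading_prob: float = 0.3
    cis_prob: float = 0.15
    trans_prob: float = 0.005
    lfc_sd: float = 1.0
    min_abs_lfc: float = 0.5
    interaction_prob: float = 0.02
    antagonistic_frac: float = 0.96
    cancellation_frac: float = 1.0  # 1 = exact antagonistic cancellation
    seed: int = 0

    def __post_init__(self):
        for p in (self.cis_prob, self.trans_prob, self.interaction_prob,
                  self.antagonistic_frac, self.batch_loading_prob):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.dispersion[0] < 0:
            raise ValueError("dispersion must be non-negative")


def _draw_lfc(rng, config) -> float:
    """Effect size on the natural-log scale, bounded away from zero."""
    lfc = rng.normal(0.0, config.lfc_sd)
    if abs(lfc) < config.min_abs_lfc:
        lfc = np.sign(lfc or 1.0) * config.min_abs_lfc
    return float(lfc)


def simulate_counts(config: ExprSimConfig) -> tuple[ExprDataset, pd.DataFrame]:
    """Simulate an RNA-seq count dataset over the CSS panel with ground truth.

    count[g, s] ~ NegBin(mean = (lib_s / mean_lib) * exp(eta_g + x_s.beta_g
    + z_s.lambda_g), dispersion phi_g) with x_s the design row of sample s and
    z_s latent batch factors.  Cis main effects land only on genes located on
    the relevant substituted chromosome; interaction effects are antagonistic
    (cancelling the main-effect sum) with probability ``antagonistic_frac``,
    otherwise synergistic.  The truth table records one row per nonzero
    gene x term effect with its class.
    """
    rng = np.random.default_rng(config.seed)
    crosses = enumerate_crosses(
        config.maternal_panel, config.paternal_panel, config.exclusions
    )
    n_ctrl, n_single, n_double = config.replicates
    sample_rows = []
    for cross in crosses:
        n = (n_ctrl, n_single, n_double)[cross.n_substitutions]
        for _ in range(n):
            sample_rows.append((cross.maternal_sub, cross.paternal_sub))
    samples = pd.DataFrame(sample_rows, columns=["maternal_sub", "paternal_sub"])
    samples.index = pd.Index(
        [f"S{i:03d}" for i in range(len(samples))], name="sample_id"
    )
    dm = build_design_matrix(samples, include_interactions=True)
    X = dm.X.drop(columns="Intercept")
    terms = list(X.columns)
    term_chroms = {}
    for t in terms:
        if t.startswith("int"):
            term_chroms[t] = set(t[3:].split(":"))
        else:
            term_chroms[t] = {t[3:]}

    genes = pd.Index([f"G{i:05d}" for i in range(config.n_genes)], name="gene_id")
    chroms = list(config.chrom_sizes)
    probs = np.array([config.chrom_sizes[c] for c in chroms], dtype=float)
    probs /= probs.sum()
    gene_chrom = pd.Series(
        rng.choice(chroms, size=config.n_genes, p=probs), index=genes, name="chrom"
    )

    eta0 = rng.normal(*config.baseline_log_mean, size=config.n_genes)
    phi = config.dispersion[0] * 10 ** rng.normal(
        0.0, config.dispersion[1], size=config.n_genes
    )
    # mean-dispersion trend: small-count genes are noisier
    phi = phi + config.dispersion_trend_scale / np.exp(eta0)

    lib = config.mean_lib_size * 10 ** rng.normal(
        0.0, config.lib_size_log10_sd, size=len(samples)
    )
    lib_sizes = pd.Series(lib, index=samples.index, name="lib_size")

    Z = rng.normal(size=(len(samples), config.n_batch)) if config.n_batch else None
    beta = np.zeros((config.n_genes, len(terms)))
    truth_rows = []
    main_terms = [t for t in terms if not t.startswith("int")]
    int_terms = [t for t in terms if t.startswith("int")]
    gc = gene_chrom.to_numpy()

    for j, t in enumerate(main_terms):
        chrom = next(iter(term_chroms[t]))
        on_chrom = gc == chrom
        p_hit = np.where(on_chrom, config.cis_prob, config.trans_prob)
        hit = rng.random(config.n_genes) < p_hit
        for g in np.flatnonzero(hit):
            lfc = _draw_lfc(rng, config)
            beta[g, terms.index(t)] = lfc
            klass = "main-cis" if on_chrom[g] else "main-trans"
            truth_rows.append((genes[g], t, lfc, klass))

    for t in int_terms:
        jt = terms.index(t)
        m, p = t[3:].split(":")
        jm, jp = terms.index(f"mat{m}"), terms.index(f"pat{p}")
        hit = rng.random(config.n_genes) < config.interaction_prob
        antag = rng.random(config.n_genes) < config.antagonistic_frac
        for g in np.flatnonzero(hit):
            a, b = beta[g, jm], beta[g, jp]
            if antag[g]:
                if a == 0.0 and b == 0.0:
                    # antagonism needs a main effect to cancel; plant one
                    a = _draw_lfc(rng, config)
                    beta[g, jm] = a
                    klass_m = "main-cis" if gc[g] == m else "main-trans"
                    truth_rows.append((genes[g], f"mat{m}", a, klass_m))
                eff = -config.cancellation_frac * (a + b)
                klass = "interaction-antagonistic"
            else:
                direction = np.sign(a + b) or (1.0 if rng.random() < 0.5 else -1.0)
                eff = direction * abs(_draw_lfc(rng, config))
                klass = "interaction-synergistic"
            if eff != 0.0:
                beta[g, jt] = eff
                truth_rows.append((genes[g], t, float(eff), klass))

    eta = eta0[:, None] + beta @ X.to_numpy().T
    if Z is not None:
        lam = rng.normal(0.0, config.batch_loading_scale,
                         size=(config.n_genes, config.n_batch))
        lam *= rng.random(lam.shape) < config.batch_loading_prob
        eta = eta + lam @ Z.T
    mu = (lib / config.mean_lib_size)[None, :] * np.exp(eta)

    if np.all(phi == 0):
        counts = rng.poisson(mu)
    else:
        shape = 1.0 / np.maximum(phi, 1e-12)
        gam = rng.gamma(shape[:, None], 1.0 / shape[:, None], size=mu.shape)
        counts = rng.poisson(mu * gam)
    counts_df = pd.DataFrame(counts.astype(np.int64), index=genes,
                             columns=samples.index)

    dataset = ExprDataset(
        counts=counts_df, samples=samples, gene_chrom=gene_chrom,
        lib_sizes=lib_sizes,
    )
    truth = pd.DataFrame(
        truth_rows, columns=["gene", "term", "coefficient", "class"]
    )
    return dataset, truth


_PROFILES = {
    # <=200 genes, <=60 samples; runs end to end in well under a minute
    "tiny": dict(
        pheno=dict(
            maternal_panel=("3", "6"),
            paternal_panel=("4", "8"),
            exclusions=(),
            cell_sizes=(12, 8, 8),
        ),
        expr=dict(
            n_genes=160,
            maternal_panel=("3", "6"),
            paternal_panel=("4", "8"),
            exclusions=(),
            replicates=(10, 5, 5),
            cis_prob=0.3,
            interaction_prob=0.05,
        ),
    ),
    # the full panel at the published replicate structure
    "paper-like": dict(
        pheno=dict(),  # PhenoSimConfig.paper_like defaults
        expr=dict(n_genes=13000, replicates=(20, 8, 5)),
    ),
}


def make_fixture(profile_name: str, out_dir, seed: int = 0) -> dict[str, Path]:
    """Write CSV/TSV/BED fixture files (plus truth tables) for a named profile.

    Returns a dict of logical name -> written path.  Byte-identical for the
    same profile and seed.
    """
    if profile_name not in _PROFILES:
        raise ValueError(f"unknown profile {profile_name!r}; "
                         f"choose from {sorted(_PROFILES)}")
    prof = _PROFILES[profile_name]
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    if profile_name == "paper-like":
        pheno_cfg = PhenoSimConfig.paper_like(seed=seed)
    else:
        pheno_cfg = PhenoSimConfig(seed=seed, **prof["pheno"])
    table, pheno_truth = simulate_phenotypes(pheno_cfg)

    expr_cfg = ExprSimConfig(seed=seed + 1, **prof["expr"])
    dataset, expr_truth = simulate_counts(expr_cfg)

    paths = {
        "pheno": out / "pheno.csv",
        "pheno_truth": out / "pheno_truth.tsv",
        "counts": out / "counts.tsv",
        "samples": out / "samples.tsv",
        "genes": out / "genes.bed",
        "expr_truth": out / "expr_truth.tsv",
    }
    ptab = table.copy()
    for col in ("maternal_sub", "paternal_sub"):
        ptab[col] = ptab[col].fillna("")
    ptab.to_csv(paths["pheno"], index=False, float_format="%.6g")
    pheno_truth.to_csv(paths["pheno_truth"], sep="\t", index=False)
    dataset.counts.to_csv(paths["counts"], sep="\t")
    stab = dataset.samples.copy()
    for col in ("maternal_sub", "paternal_sub"):
        stab[col] = stab[col].fillna("")
    stab.to_csv(paths["samples"], sep="\t")
    # synthetic BED: 1 Mb placeholder intervals; only the chromosome is used
    bed = pd.DataFrame(
        {
            "chrom": ["chr" + c for c in dataset.gene_chrom],
            "start": np.arange(dataset.n_genes) * 1_000_000,
            "end": np.arange(dataset.n_genes) * 1_000_000 + 1_000_000,
            "gene_id": dataset.gene_chrom.index,
        }
    )
    bed.to_csv(paths["genes"], sep="\t", index=False, header=False)
    expr_truth.to_csv(paths["expr_truth"], sep="\t", index=False)
    return paths
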