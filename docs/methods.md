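# Methods

This note documents the models, the synthetic-data generators, the numerical
choices, and the limitations of `cssmap`.

## Design model

A cross in a CSS panel is labelled by its maternal and paternal substituted
chromosome (or none); with maternal panel {3, 6, 14, 17} and paternal panel
{4, 5, 8, 10} there are 25 cross types (control, 8 singles, 16 doubles).
The design matrix uses treatment coding against the control cross: an
intercept, one 0/1 indicator per maternal substitution level, one per
paternal level, and one product column per maternal×paternal pair observed
in the data. Interaction columns are exact elementwise products of their
parent main-effect columns; dropping them yields the "average-effect"
(additive) design. Columns are ordered deterministically (maternal panel
sorted, then paternal, then pairs lexicographically) so coefficient vectors
are reproducible. Chromosome ids are opaque strings, so custom labels or X
work unchanged. Reference coding is fixed; there is no sum-to-zero option,
because every reported effect is a contrast against the control strain.

Cells (cross × sex) smaller than `min_cell` (default 5 animals) are removed
before fitting: the animals are dropped and, because interaction columns
exist only for observed pairs, the corresponding interaction column
disappears while main-effect columns survive through the remaining cells.
Removal operates per cross × sex, not per cross, so a cross can remain
analyzable in one sex. A rank check rejects designs where an interaction
column duplicates a main column (an unsupported double cross), naming the
offending column.

## Trait pipeline

**Winsorization.** The pooled trait vector (both sexes, all crosses) is
capped at median + k·MAD with k = 4 and MAD the *raw* (unscaled) median
absolute deviation; no floor is applied, so only high outliers are affected
and the operation is idempotent. The result also reports the ceiling under
the 1.4826-scaled MAD convention, since the two conventions differ by a
factor ~1.5 and downstream users may want to compare both. Rationale for
the raw default: "k median absolute deviations" read literally, with the
scaled variant exposed rather than hidden.

**Per-sex models.** Ordinary least squares of the trait on the design, fit
separately per sex because both the residual variance and the genetic
effects may differ between sexes. Each fit reports coefficients, the OLS
covariance, and both R² and adjusted R². Joint F-tests of "no main effects"
and "no interaction effects" use the Wald quadratic form on the coefficient
covariance, which for OLS equals the nested residual-SS F exactly (tested
against that oracle). The two per-sex p-values for each hypothesis are
combined with Fisher's method (−2Σln p ~ χ² with 4 df). A combined-sexes
model with a sex indicator is provided as the alternative parameterization.

**IVW combination.** Per term, the female and male estimates are combined
with inverse-variance weights; a term estimable in only one sex (its cell
was removed in the other) passes through with full weight on that sex.

**Studentized bootstrap + maxT.** Each of B replicates (default 10,000)
resamples animals with replacement independently within every cross × sex
cell — implemented as multinomial case weights, which is algebraically a
refit of the expanded resample — refits both sex models, IVW-combines every
coefficient, and studentizes against the replicate's own combined standard
error: t* = (β* − β̂)/SE*. Raw p-values invert the |t*| distribution;
confidence intervals are percentile-t around β̂. Family-wise adjustment
compares each observed |t| to the bootstrap distribution of max|t*| over
its family — all main-effect terms form one family and all interaction
terms another, separately per trait — with the (1 + count)/(B + 1)
estimator so no p-value is exactly zero. The whole IVW statistic is
bootstrapped (resample → per-sex fit → combine → studentize) so that one
adjusted p-value exists per term. Cells of size 1 trigger a degenerate-
resample warning. Family-wise error calibrates to ~0.05 on all-null
simulations (checked at B = 2000 over 400 simulated experiments).

**Interaction share of heritable variation.** (R²adj_full −
R²adj_additive)/R²adj_full per sex, undefined (flagged, not clipped) when
R²adj_full ≤ 0; its CI comes from the same within-cell bootstrap. Adjusted
R² is used to counter the full model's extra parameters.

## Expression pipeline

**Sample QC.** A sample is removed when its median pairwise Spearman
correlation of log₂ CPM against all other samples falls more than 5 raw
MADs *and* at least 0.05 correlation units below the cohort median. The
absolute floor exists because in a homogeneous cohort the MAD of these
medians is ~0.003 and a pure MAD rule flags innocent samples. Flagging
more than 20% of samples raises an error (systemic problem, not outliers).

**Expression filter.** A gene is kept iff ≥ 75% of samples have a count
≥ 15; the boundary is inclusive (exactly 75% keeps the gene).

**Surrogate covariates.** Latent batch structure is estimated from genes
with no evidence of genetic regulation: per-gene F-tests of the design on
log-CPM select design-null genes (p > 0.5), and the surrogates are the top
k (default 5) principal components of their centered log expression,
unit-norm with a fixed sign convention. A plain residual-PCA variant
(projecting the design out of all genes first) is available as
`method="residual"` but is *not* the default: when a batch factor is
incidentally correlated with the design, residual PCA recovers only its
design-orthogonal part, and the remaining design-space component
contaminates the genetic coefficients — in simulation this inflated the
null per-term rejection rate to 7–12% at α = 0.05 and the interaction-call
false discovery proportion to ~50%. The null-gene estimator restores
calibration and recovers a planted batch factor with |r| > 0.9.

**Per-gene count models.** A log-link negative-binomial GLM (variance
μ + φμ²) of counts on design + surrogates with a log library-size offset,
fit by Fisher-scoring IRLS (verified to 1e-9 against an independent GLM
implementation). Additivity on the link scale is a multiplicative model on
the expression level. Dispersion φ is estimated per gene by Cox–Reid
adjusted profile likelihood (bounded search on log φ) and shrunk toward a
lowess mean–dispersion trend with weight prior_df/(prior_df + residual df),
prior_df = 10 by default; the exact weighting is a pragmatic choice
validated by the calibration simulations rather than a replication of any
specific tool's numerics. Quasi-likelihood dispersions s²_g =
deviance/df are squeezed across genes with an empirical-Bayes scaled-F
prior (moment matching on log s², as in standard moderated-statistics
practice); tests are moderated F statistics: deviance-drop F for the two
joint nulls (all strains equal; all interactions zero) and Wald F per
genetic term, all on (df₁, df_resid + prior df). Under global-null Poisson
simulation the joint-test p-values are uniform (KS p > 0.01). Genes whose
IRLS does not converge are reported in `failed`, never silently dropped.

**QTL calls.** meQTLs (per substituted chromosome term) and ieQTLs (per
chromosome-pair term) with cis/trans labels: cis iff the gene lies on a
substituted chromosome of the term (either of the two for a pair).
Benjamini–Hochberg runs independently within each stratum — (chromosome or
pair) × (cis/trans) — which is more powerful when signal density differs by
stratum; calls are significant at q < 0.05. Output ordering is
deterministic with q-ties broken by gene id. Summaries report, per term,
the percentage of expressed genes with cis calls (denominator: expressed
genes on the term's chromosome(s)) and trans calls (the complement
denominator — the two denominators partition the expressed genes), distinct
QTL counts per gene, and the Spearman correlation of cis vs trans
percentages across terms.

**Classification.** For each significant interaction, model-fitted means
(covariates zeroed, reference library) give the control, single and double
expectations; the additive prediction is μₐμᵦ/μ₀ on the expression scale
(sum of deviations for traits on the linear scale). Departure from control
is measured on the model scale — |log(μ/μ₀)| for expression — so the class
reduces to comparing |a + b + i| with |a + b| in the log-scale
coefficients; synergistic when the observed double departs more than
predicted, antagonistic when less, exact ties labelled additive and
excluded from the tally. Fitted means rather than raw group averages keep
the classification consistent with the model that declared the interaction
significant. Reversion to control is a moderated contrast of the double
cross against control (β_mat + β_pat + β_int on the log scale); the double
cross is "reverted" when p > 0.1.

**Variance partition.** Per gene, fitted values are computed from the
genetic terms only — surrogate covariates zeroed and no library offset, so
the fitted value is constant within a strain and the sum of mean-centered
squares measures between-strain variation (with a common offset the
proportion would be identical; excluding it makes the invariance to library
rescaling exact). The interaction share is (SS_full − SS_additive)/SS_full,
reported unclipped and flagged when SS_full = 0, and only interpreted for
genes passing the genetic-control gate (plain BH across genes on the
all-strain joint test, q < 0.05). The sums are unweighted, as the
definition literally states. The estimator is biased upward by overfitting;
the bound comes from simulating counts per gene from a Poisson around the
additive fit (covariates and offsets included, so the simulated data match
everything except interactions), refitting both models, and averaging the
share over replicates (default 100). The bias is positive and shrinks with
replicate count. Quartiles everywhere use the median-unbiased definition.

## Synthetic data

The phenotype generator draws trait = per-sex baseline + maternal main +
paternal main + interaction + Normal(0, per-sex SD), with defaults
emulating the study conditions: glucose baseline ≈ 108/112 mg/dL (F/M) with
SD ≈ 14–16 mg/dL, weight ≈ 16/18 g with SD ≈ 1.4–1.6 g, cells of 40/15/14
animals per sex (control/single/double, ~770 animals over the panel), and
rare (0.7%) large positive glucose outliers — positive only, so a
winsorization ceiling can remove them. `PhenoSimConfig.paper_like()` plants
glucose main effects of 15.6–25 mg/dL on chromosomes 3, 4 and 5 and five
antagonistic interactions constructed as exact cancellation
(interaction = −(mainₘ + mainₚ)), so double crosses revert to baseline;
body weight gets two modest main effects and no interactions.

The count generator draws count ~ NegBin(mean = librel · exp(η₀ + x·β +
z·λ), φ) with genes assigned to 19 autosomes proportionally to physical
size, baseline log-means Normal(5, 1.2) (median ~150 counts), lognormal
dispersions around 0.05 plus a 1/mean trend component, lognormal library
sizes, and 2 Gaussian latent batch factors with sparse loadings (the
minimal structure a surrogate-variable stage can be validated against).
Replicates default to 20/8/5 (control/single/double, males only) with one
excluded double cross. Main effects are cis-enriched (probability 0.15 on
the substituted chromosome vs 0.005 elsewhere); interactions occur with
probability 0.02 per pair and are antagonistic 96% of the time,
constructed as exact cancellation on the log scale by default (partial
cancellation configurable); synergistic interactions push further in the
main-effect direction. Effect sizes are Normal(0, 1) on the natural-log
scale bounded away from zero at |log FC| ≥ 0.5, matching the magnitude of
detected-eQTL examples (~2–4 fold). Every nonzero effect is recorded in a
truth table (gene/trait, term, coefficient, class).

What the generators do *not* emulate: genuine read-level artifacts
(mapping bias, duplicates), within-chromosome gene–gene correlation,
non-Gaussian trait residuals beyond injected outliers, sex-specific
expression (the expression arm is male-only by design), and selection
effects of real breeding. Passing tests therefore demonstrate statistical
correctness of the machinery under the assumed model, not robustness to
every artifact of a real experiment.

## Numerical choices and degenerate inputs

- IRLS: Fisher scoring with working weights μ/(1 + φμ), linear predictor
  clipped at ±30, convergence on relative deviance change < 1e-10 plus
  step size < 1e-8, max 60 iterations; initialization from a least-squares
  fit of log(y + mean/8) − offset.
- Dispersion search: bounded Brent on log φ ∈ [log 1e-8, log 30], xatol
  0.01, with an explicit comparison against the Poisson boundary.
- Variance squeezing: if the observed spread of log s² is below the
  χ²-implied spread, the prior df is effectively infinite (1e6) and all
  genes share the common variance.
- Winsorize with MAD = 0 (all values identical) warns and degenerates to
  ceiling = median. Fisher's method rejects p = 0. IVW rejects
  non-positive variances. Bootstrap warns for B < 100 and for cells of
  size 1. Reversion testing needs ≥ 2 values per group; zero-variance
  groups give p = 1 (equal means) or 0.
- All randomness flows through `numpy.random.default_rng`; pipeline stages
  derive named substreams from one top-level seed via `SeedSequence` with a
  CRC of the stage name, so stages are independently reproducible.

## Scaling of the shipped analyses

The test suite and the acceptance script run simulations scaled to minutes
on a single CPU: expression runs use 500–1200 genes (the machinery is
linear in genes; the published scale of ~13,000 genes is exercised only
through `make_fixture("paper-like")`), the family-wise-error calibration
uses a reduced 2×2 panel at B = 2000 over 200 experiment replicates, and
the additive-null bias simulation uses 30–60 gated genes × 20–30
replicates. These sizes are the package's own defaults for its shipped
checks; all of them are parameters.

## Known limitations

- The NB machinery is this package's own moderated-QL implementation; it
  matches an independent GLM implementation coefficient-for-coefficient and
  calibrates in simulation, but it does not numerically replicate any named
  tool's dispersion shrinkage, and is not meant to.
- The surrogate estimator assumes most genes are not genetically regulated;
  with < max(10k, 50) design-null genes it falls back to residual PCA with
  a warning.
- Trait models are fixed-effect OLS: no covariates beyond sex, no mixed
  models, no parent-of-origin decomposition beyond the maternal/paternal
  coding, no X-dosage handling.
- The heritable-share estimator inherits adjusted-R²'s instability when
  total genetic signal is weak (shares outside [0, 1] are reported raw and
  flagged).
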