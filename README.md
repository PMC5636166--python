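# cssmap

Epistasis mapping for mouse chromosome substitution strain (CSS) crosses.

## The problem

In a CSS panel, a single chromosome of a host strain (C57BL/6J, "B6") is
replaced by the homolog from a donor strain (A/J). Crossing a maternal CSS
with a paternal CSS yields F1 animals heterozygous for up to two donor
chromosomes on an otherwise fixed background, so the panel of control,
single and double crosses directly exposes pairwise inter-chromosomal
epistasis: does the double substitution deviate from what the two single
substitutions predict additively?

`cssmap` implements the full analysis for such a panel, for quantitative
traits (body weight, fasting glucose) and for gene-level RNA-seq counts:

- **Trait pipeline** — one-sided winsorization at median + 4·MAD; per-sex
  OLS with maternal, paternal and interaction indicators (reference = B6);
  joint F-tests per term class combined across sexes by Fisher's method;
  per-term inverse-variance-weighted (IVW) combination
  β̂ᴵⱽᵂ = w·β̂ᶠ + (1−w)·β̂ᵐ, w = (1/var β̂ᶠ)/(1/var β̂ᶠ + 1/var β̂ᵐ);
  a studentized bootstrap resampling within every cross×sex cell with maxT
  family-wise adjustment (main effects and interactions as separate
  families); and the interaction share of heritable variation,
  (R²adj_full − R²adj_additive)/R²adj_full.
- **Expression pipeline** — correlation-based sample QC; the ≥15-counts-in-
  ≥75%-of-samples expression filter; surrogate covariates for latent batch
  structure; per-gene log-link negative-binomial GLMs (departure from
  additivity = departure from a multiplicative model) with Cox–Reid
  dispersions shrunk to a mean–dispersion trend and moderated
  quasi-likelihood F tests; meQTL/ieQTL calls with cis/trans labels under
  Benjamini–Hochberg FDR stratified by chromosome (pair) × cis/trans;
  synergistic/antagonistic classification against the multiplicative
  prediction μₐμᵦ/μ₀ with a reversion-to-control contrast (reverted iff
  p > 0.1); and a per-gene partition of genetic variation,
  (SS_full − SS_additive)/SS_full, gated on an all-strain joint test and
  bias-bounded by a Poisson additive-null simulation.
- **Synthetic data** — generators for phenotype tables and count matrices
  with the panel's structure and known ground truth, so every stage is
  testable without any external download.

## Worked example

```python
from cssmap import PhenoSimConfig, simulate_phenotypes, analyze_trait

cfg = PhenoSimConfig.paper_like(seed=3)   # 768 animals, 25 cross types,
table, truth = simulate_phenotypes(cfg)   # 5 antagonistic glucose interactions
res = analyze_trait(table, "glucose_mg_dl", winsorize_k=4, B=2000, seed=1)

w = res.winsorization
print(f"ceiling {w.ceiling:.1f} mg/dL, {w.n_modified} observations capped")
for e in res.bootstrap.effects:
    if e.term_class == "interaction" and e.adj_p < 0.05:
        print(f"{e.term}: {e.estimate:+.1f} mg/dL, adj p = {e.adj_p:.4f}")
for s, h in res.shares.items():
    print(f"interaction share ({s}): {h.proportion:.2f} "
          f"[{h.ci_low:.2f}, {h.ci_high:.2f}]")
```

prints (seed 3):

```
ceiling 163.9 mg/dL, 5 observations capped
int3:4: -40.5 mg/dL, adj p = 0.0005
int3:5: -45.2 mg/dL, adj p = 0.0005
int6:5: -18.8 mg/dL, adj p = 0.0030
int14:4: -15.6 mg/dL, adj p = 0.0275
interaction share (F): 0.68 [0.52, 0.81]
interaction share (M): 0.60 [0.48, 0.73]
```

Four of the five planted antagonistic interactions reach family-wise
significance at B = 2000 in this draw; the share numbers say that roughly
60–70% of the heritable glucose variation is attributable to interactions
rather than additive chromosome effects — the antagonistic interactions
cancel main effects in the double crosses, so an additive-only model
explains far less.

The same pipelines are exposed on the command line (`cssmap simulate-pheno`,
`analyze-pheno`, `analyze-expr`, `call-qtls`, `classify`, `varpart`,
`report`); see `cssmap --help`.

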