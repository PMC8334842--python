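# phylometa

Bayesian phylogenetic meta-analysis of inbreeding avoidance across species.

Comparative studies measure how related mated pairs are (*rPairs*) and how
related a random male–female pair in the same population would be
(*rAverage*). If animals avoid inbreeding, pairs are less related than
chance; if they mate randomly, the two quantities track each other 1:1.
This package implements the full analysis pipeline for such data, for
researchers doing phylogenetic comparative meta-analysis:

- **Effect sizes** — relatedness correlations become Fisher-Z values,
  `Zr = ½ ln((1+r)/(1−r))`, with sampling variance `1/(n−3)`;
  inbred-vs-outbred group summaries (mean/SD/n) become a depression effect
  size via a standardized mean difference, `r = d/√(d² + a)`,
  `a = (n₁+n₂)²/(n₁n₂)`.
- **Phylogeny** — Newick trees (via dendropy) become the phylogenetic
  correlation matrix **A** (shared root-to-tip path lengths, unit diagonal)
  used as the covariance of a species-level random effect.
- **MCMC engine** — a from-scratch Gibbs sampler for the meta-regression
  `y_i = x_i'β + a_i + e_i + m_i` with `a ~ N(0, σ²_phylo·A)`,
  `e ~ N(0, σ²_resid·I)` and known measurement-error variances
  `m_i ~ N(0, v_i)`; binomial (logit) responses use latent liabilities with
  adaptive Metropolis steps. Priors: N(0, 10¹⁰) on fixed effects,
  inverse-gamma (V = 1, ν = 0.002) on variances.
- **Summaries** — posterior means, equal-tail 95% credible intervals, pMCMC
  (twice the smaller tail proportion, floored at 2/N), effective sample
  sizes, Gelman–Rubin PSRF across chains, phylogenetic heritability
  `H² = σ²_p/(σ²_p+σ²_r)`, total heterogeneity
  `I²_total = (σ²_p+σ²_r)/(σ²_p+σ²_r+σ²_m)`, and marginal R².
- **Model suite** — the eight-model battery for inbreeding-avoidance data
  (intercept-only heterogeneity models; the ZrPairs~ZrAverage slope-vs-1
  test; depression, mechanism and cooperative-breeding interactions;
  binomial mechanism/random-mating models) plus publication-bias
  diagnostics (funnel data, Egger-style and time-lag regressions).
- **Synthetic data** — a generator that emulates the comparative dataset
  with known ground truth, so every stage is testable end to end.

## Worked example

```bash
python examples/03_fit_avoidance_model.py
```

```
Model 2 (n = 41 species, 3 chains, 3000 pooled draws)
  slope of ZrAverage : PM = 0.27, CI = -0.15 to 0.72 (PSRF 1.003)
  deviation from 1   : PM = -0.73, CI = -1.15 to -0.28, pMCMC = 0.003
  R2_marginal        : 0.08
```

The synthetic dataset mixes species with inbreeding depression (generated
with a shallow slope of 0.2 — they decouple mate relatedness from
population relatedness) and species without depression (slope 1 — random
mating). The fitted slope sits between the two, and its deviation from 1 is
credibly negative: the expected signature of inbreeding avoidance. The
other scripts in `examples/` walk through effect-size construction, the
generator, heterogeneity/interaction models and the publication-bias
battery.

The same pipeline runs from the shell:

```bash
phylometa simulate --seed 42 --out data/
phylometa suite --data data/dataset.csv --tree data/tree.nwk --out results/
phylometa pubbias --data data/dataset.csv --tree data/tree.nwk --out results/
```

Every run writes a `manifest.json` (config, seeds, input checksums) from
which it can be reproduced bit-identically.

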