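# Methods

## The model

The unit of analysis is one species with a Fisher-Z effect size and a known
sampling variance. For a response vector *y* over *k* species the Gaussian
hierarchy is

    y_i = x_i'β + a_i + e_i + m_i
    a ~ N(0, σ²_phylo · A),   e ~ N(0, σ²_resid · I),   m_i ~ N(0, v_i)

where **A** is the phylogenetic correlation matrix and the `v_i` are the
known sampling variances (`1/(n_i − 3)` for z-transformed correlations).
The `m` term is what makes this a *meta*-regression: each data point is
weighted by its inverse sampling variance, and σ²_m (the "typical"
measurement-error variance, Higgins' formula
`σ²_m = (k−1)Σw / ((Σw)² − Σw²)`, `w_i = 1/v_i`) enters the heterogeneity
statistic

    H² = σ²_p / (σ²_p + σ²_r),   I²_total = (σ²_p + σ²_r) / (σ²_p + σ²_r + σ²_m).

An alternative σ²_m (plain mean of the `v_i`) is selectable via
`higgins_sigma2_m(..., method="mean")`. Binomial responses (mechanism
presence, random mating, expanded by pair counts) use a latent liability
`l_i` with `y_i ~ Binomial(n_i, logistic(l_i))` and `l = Xβ + a + e`.

Priors follow standard practice for these models: independent N(0, 10¹⁰) on
fixed effects and inverse-gamma on variance components with shape ν/2 and
rate νV/2 for V = 1, ν = 0.002. Reference chain lengths are 2 000 000
iterations (1 000 000 burn-in, thin 1000) for Gaussian and 6 000 000
(burn-in 1 000 000, thin 5000) for binomial models
(`REFERENCE_GAUSSIAN_SETTINGS` / `REFERENCE_BINOMIAL_SETTINGS`); everything in the
test and acceptance suites runs at desk scale (below).

## Samplers

Gaussian fits use blocked Gibbs. The phylogenetic effects are updated in
the eigenbasis of **A** (`A = QΛQ'`), where their full conditional
covariance is diagonal, so one sweep costs O(k²) with no per-sweep matrix
decompositions; β is a conjugate multivariate-normal block, the `m_i` are
independent normals, and the variances are conjugate inverse-gamma.
Eigenvalues of **A** are floored at 1e−10 to tolerate numerically singular
trees. When a test fixes σ²_resid = 0, the `m` latents are analytically
integrated out (conditioning on them would freeze the chain); β then sees
heteroscedastic noise `diag(v)` directly.

Binomial fits keep β, a and σ²_phylo conjugate given the liabilities and
update each liability with a univariate random-walk Metropolis step.
Liabilities are conditionally independent given the other blocks, so the
update vectorizes across species. Proposal scales adapt every 50 burn-in
iterations toward 44% acceptance and freeze afterwards. The liability-scale
residual variance is not identifiable from binomial data and is fixed
(default 1.0, `binomial_residual_fix`); estimates are reported on the
latent logit scale without heritability rescaling, and per-level
probabilities are posterior logistic transforms of the level liabilities
(population level, residual not integrated over).

Posterior summaries are equal-tail 2.5/97.5 percentiles (not HPD); pMCMC is
`2·max(1, min(#above, #below))/N`, so it is never exactly zero; ESS uses
the initial-positive-sequence autocorrelation estimator; the convergence
diagnostic is the classic Gelman–Rubin PSRF over chains. Marginal R² is
`var(Xβ)/(var(Xβ)+σ²_p+σ²_r)` per draw (sample variance of the fitted
fixed part); intercept-only models report 0 by convention. When several
chains are run, the suite reports parameters from one chain chosen at
random (seeded and recorded) and uses all chains for PSRF.

## Design choices where the design was open

- **d→r conversion**: pooled-SD Cohen's d (no small-sample correction),
  `r = d/√(d²+a)`, `a = (n₁+n₂)²/(n₁n₂)`; variance propagated from
  `v_d = (n₁+n₂)/(n₁n₂) + d²/(2(n₁+n₂))` by the delta method through r and
  the z-transform. Sign convention: positive ZrDepression means inbreeding
  reduces fitness.
- **Factor coding**: treatment contrasts with explicit reference levels
  (depression = no, mechanism = none, cooperative = no). All reported level
  differences are computed from raw posterior draws, so the coding cannot
  change them.
- **Duplicate populations** are averaged on the correlation scale before
  the z-transform; sample sizes are averaged (rounded) as well.
- **`not_mentioned` depression reports** are analysed as `yes` (species
  lacking any report are assumed to suffer inbreeding depression) in a
  separate `depression_analysis` column; the original report is retained.
- **Model 4** (does having *any* avoidance mechanism depend on inbreeding
  depression?) is fitted on all species: its fixed effect is the
  depression class itself, so the yes/no contrast requires both classes.
  Models 5–8 are fitted on the depression subset (Model 8 additionally
  drops taxa whose breeding system cannot be classified as cooperative or
  not, e.g. a social insect).
- **Trees without branch lengths** get Grafen heights (descendant-tip
  count − 1); non-ultrametric trees are rescaled to the mean root-to-tip
  depth with a warning (or rejected with `strict=True`).
- **Covariates are not error-weighted**: only responses carry the `mev`
  term, so regressions of ZrPairs on ZrAverage inherit the usual
  attenuation from noise in the observed covariate. The recovery and
  calibration batteries therefore simulate from the fitted model (covariate
  fixed); the full generator, which adds noise to both axes, shows the
  attenuation one should also expect in real data.

## The synthetic generator

`simulate.generate` emulates the comparative dataset: a unit-height Yule
tree (pure birth, in-package for exact seed determinism); latent ZrAverage
per species (mean 0.05, phylogenetic variance 0.05, residual 0.02); latent
ZrPairs with class-specific slopes on ZrAverage (0.2 where inbreeding
depression is present, 1.0 where it is not — i.e. non-avoiders mate at
random); observation noise N(0, 1/(n−3)) on both axes with n_pairs uniform
on [10, 100] and n_average on [50, 200] (population-level relatedness is
typically estimated over many more dyads than there are breeding pairs);
41 species of which a fraction 34/41 has depression; mechanisms only in
depression species with probabilities 9/34, 9/34, 5/34, 11/34 (active mate
choice, sex-biased dispersal, post-mating, none); random mating with
mechanism-dependent probabilities (0.01, 0.58, 0.34, 0.89); and
inbred/outbred group summaries (means 0.7 vs 1.0, SD 0.3, group n in
[10, 50]) for roughly 16/34 of depression species. Depression status is
assigned i.i.d. across species (the trait is labile over the phylogeny);
there is no phylogenetic signal in any categorical assignment. What the
generator does *not* emulate: within-species heterogeneity of relatedness
estimators, non-Gaussian effect-size errors, correlated sampling of
rPairs and rAverage within a study, or study-level (as opposed to
species-level) clustering — so passing tests demonstrate correctness of
the machinery under the stated model, not robustness to those features of
real data.

`simulate_funnel_dataset` is the calibration fixture for the
publication-bias battery: an intercept-only funnel with a common positive
mean (0.5), small heterogeneity (σ²_p = 0.01, σ²_r = 0.005), study sizes
n ∈ [4, 200] and 80 effect sizes. The direction matters: censoring on
|Zr| of a sign-symmetric funnel changes the spread but not the mean of
low-precision effects, so no *signed* Egger slope is induced; publication
bias presupposes a preferred direction. The size matters too: inverse-
variance weighting downweights exactly the biased low-precision records,
and at ~40 effect sizes the Egger CI is as wide as the induced slope.
`censor_for_bias(strength)` removes records that are below the median in
both precision and |effect| with probability `strength`.

## Desk-scale settings and problem sizes

Replicate batteries (GLS agreement, slope recovery, type-I, bias-test
calibration) run 100 datasets each with single chains of 6000 iterations
(burn-in 1000, thin 5; 1000 retained draws) — the Gibbs sampler's ESS per
draw is near 1 for these models, so calibration matches longer runs.
Convergence and determinism checks run the Gaussian fixture suite at
3 × 30 000 iterations. The binomial Models 4 and 7 are quasi-separated by
construction whenever mechanisms occur only in depression species (entire
factor levels with all-zero or all-n responses); under the diffuse fixed-
effect prior their separated coefficients have essentially unbounded
posteriors, credible intervals for the corresponding probabilities touch
0 or 1, and PSRF is not expected to converge for those coefficients. This
is a property of the design, documented rather than "fixed"; convergence
assertions therefore cover the Gaussian models.

## Known limitations

- Single-response models only; no pedigree covariances, parameter-expanded
  priors, or DIC/WAIC.
- The mechanism classification enters as given; no uncertainty in the
  categorical assignments is modelled.
- Equal-tail intervals can (rarely) exclude the posterior mean for very
  skewed quantities; HPD intervals are not implemented.
- The Egger and time-lag tests share the main models' random-effect
  structure; they test linear effect–SE (or effect–year) association and
  have limited power against other selection mechanisms.
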