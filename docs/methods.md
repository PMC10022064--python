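# Methods

This package implements a longitudinal ecological analysis linking changes
in a small-area public-health workforce to changes in mortality, on
municipality panels with two census periods.  Three statistical layers sit
on top of a calibrated synthetic-data generator: empirical Bayes smoothing
of standardized mortality ratios, a first-difference linear mixed model, and
a Besag–York–Mollié (BYM) spatial Poisson model fitted by full Bayesian
inference.

## Indirect standardization and EB smoothing

Expected deaths for a stratum are `e = years * sum_a pop_a * rate_a`, with
base-year national age-specific rates (five-year groups) applied to both
periods so that ratios remain comparable over time; `years = 5` because
death counts are pooled over a five-year window around each census year.
The raw SMR is `100 * o / e`.

Municipal relative risks theta are given a conjugate gamma prior fitted per
prefecture x sex x cause x period by Marshall's precision-weighted moment
estimator:

    m = sum(o) / sum(e)
    v = sum_i e_i (o_i/e_i - m)^2 / sum(e)  -  m / mean(e)

mapped to `Gamma(shape = m^2/v, rate = m/v)`.  The posterior mean
`100 (o + shape)/(e + rate)` is the EBSMR; it is a convex combination of the
raw SMR and the prior mean with weight `w = e/(e + rate)`.  Choices:

- *Moment estimator.*  Marshall's estimator is the standard recommendation
  for Poisson-Gamma EB disease mapping; the exact weighting used by older
  closed-source EB tools is not documented, so this explicit formula is the
  contract and is what the tests oracle against.
- *Non-positive moment variance* means between-area spread no larger than
  Poisson noise; the prior is then degenerate at the group mean and every
  EBSMR in the group equals `100 m` (complete shrinkage).
- *Minimum group size* for a prefecture-level prior is 5 municipalities
  (configurable); smaller groups fall back to the pooled national prior,
  since two-moment estimates from a handful of areas are unstable.
- Priors are fitted separately per sex and cause; pooling across causes
  would mix heterogeneity scales that differ by an order of magnitude.

## First-difference mixed model

One row per municipality: the change in EBSMR (follow-up minus baseline)
regressed on the change in ln(PHN per 100,000), the change in
ln(population), and plain changes of the other per-100k resources
(physicians, clinics, secondary-area general hospitals, long-term-care
welfare facilities).  Per-100k denominators use the *baseline* population
for both periods, so workforce change is not conflated with denominator
change.  The model has **no intercept** — a change model has no level — and
a prefecture random intercept absorbing prefecture-wide secular trends.

Estimation is maximum likelihood (not REML).  The single variance ratio
`lambda = sigma2_u / sigma2_e` is profiled out of the marginal Gaussian
likelihood using Sherman–Morrison identities per group, and maximized over
`[0, inf)` by a grid-plus-Brent search on log-lambda with an explicit
boundary comparison, so `lambda = 0` reduces the fit *exactly* to ordinary
least squares.  AIC counts the fixed effects plus both variance components
(one for a fit without the random effect), which makes the with/without
random-effect AIC comparison well defined.  Wald tests use a normal
reference by default; a t reference with n − p degrees of freedom is behind
a flag, since different GUI packages resolve the df convention differently.
statsmodels' MixedLM (ML) serves as an independent cross-check in the test
suite, not as the implementation, because it does not pin the boundary case.

With two periods the first-difference estimator and the within
(fixed-effects) estimator solve the same normal equations;
`first_difference_equals_fixed_effects` verifies the identity numerically
on any supplied two-period panel.

Supporting statistics: no-intercept simple regression (slope
`sum(xy)/sum(x^2)`, t on n − 1 df), variance inflation factors (auxiliary
regressions with intercept), Cohen's d with the pooled SD (undefined-d
flagged as NaN rather than silently 0), Benjamini–Hochberg step-up
q-values (via statsmodels, oracled against the raw formula), and stratified
refits below/above a baseline-population threshold of 10,000 and a
baseline-EBSMR threshold of 100.  Stratified fits keep the prefecture
random effect and fall back to OLS (logged) if the mixed fit fails.

## BYM spatial Poisson model

For stacked observations j (municipality m(j), period t(j)):

    o_j ~ Poisson(mu_j),  log mu_j = log e_j + x_j' beta + phi_m(j) + eps_j

- `phi` is an intrinsic CAR (ICAR) field on the municipality adjacency
  graph, **shared by the two periods** of a municipality (the model indexes
  the spatial effect by area, while time enters through the dummy); `eps`
  is unstructured heterogeneity per observation.
- Covariates: ln(PHN per 100k), ln(population), the four resource rates per
  100k, and a 0/1 time dummy.  All covariates except the time dummy are
  multiplied by 1/1000 before fitting so coefficient magnitudes are
  readable; summaries report both this reporting scale and the natural
  scale (reporting estimate x 1/1000... i.e. divided by 1000).
- The PHN split variant replaces ln(PHN) by a baseline column (period-0
  value on both rows) and a change column (difference of natural logs,
  switched on at follow-up by the time dummy).  The change of PHNs is a
  difference of logs, consistent with the first-difference model's
  transform.

Priors: `beta_k ~ Normal(0, 5)` **per natural covariate unit** (internally
converted through the reporting scale, so rescaling covariates for
readability cannot tighten the prior); half-Normal(1) on both scale
parameters.  The ICAR density is improper; it contributes
`-(tau/2) sum_(i~j) (phi_i - phi_j)^2` plus the rank-deficient
normalization `(n - c)/2 log tau` (c connected components).  Identification
of phi is by exact mean-centering per connected component inside the model
(the centered field enters the likelihood; the projected-out mean direction
gets a standard normal pin).  A soft sum-to-zero penalty (component mean ~
Normal(0, 0.001)) is available behind `constraint="soft"`, but the hard
projection is the default: the soft constraint makes the posterior four
orders of magnitude stiffer along the constraint direction than across it,
which a diagonal-metric sampler cannot traverse.

Sampling is by an in-package adaptive Hamiltonian Monte Carlo engine:
leapfrog integration with a diagonal mass matrix adapted from warmup
variances, step size tuned by dual averaging to a 0.9 target acceptance,
and trajectory lengths jittered over 24–56 steps.  Two structural choices
matter for this posterior:

- *Centered latent effects.*  Expected counts are in the hundreds to
  thousands, so the likelihood pins `phi` and `eps` tightly; the centered
  parameterization keeps the scale parameters well conditioned (the
  non-centered form, appropriate for weak data, inverts the funnel here).
- *Whitened regression block.*  PHN density is constructed from population,
  so the covariates are strongly collinear; beta is sampled through the
  Cholesky factor of its penalized weighted GLM Hessian (Poisson
  information discounted by the heterogeneity scale), which removes the
  correlation a diagonal metric cannot represent.  Chains start from the
  penalized IRLS mode with residuals preloaded into `eps`.

Defaults: 4 chains, 500 warmup + 500 kept draws.  Convergence is flagged at
classical split-chain R-hat < 1.05 for every reported parameter; bulk ESS
(arviz) is reported alongside.  Credible intervals are equal-tailed
empirical quantiles (2.5%/97.5% for 95%, linear-interpolation convention).
Reported `phi` draws are exactly centered per component.

Spatial confounding is inherent to BYM: effects of spatially smooth,
time-constant covariates are only weakly separated from `phi`, so their
posteriors are wide; effects carried by within-municipality change are well
identified.  This matches the behaviour the sensitivity analysis is
designed around (the change covariate, not the level, is the quantity of
interest).

## Synthetic data generator

The generator emulates the structure of a national two-census municipality
panel; defaults are calibrated to the magnitudes of the real study
population:

- 1,601 municipalities in 47 prefectures (contiguous blocks on the graph),
  periods 2010/2015.
- Populations log-normal with log-scale mu = 10.2026, sigma = 0.9961,
  chosen so the natural-scale mean and SD sit at about 44,300 and 57,700;
  a mild five-year decline (about −2% with noise).
- One national age pyramid (18 five-year groups) shared by all
  municipalities, with an optional prefecture-level old-age tilt; published
  sub-national pyramids are not modelled.
- Gompertz age-specific reference rates anchored to crude death rates of
  10.5/1000 (males) and 8.5/1000 (females) per year, with cause shares
  1.00 / 0.30 / 0.155 / 0.10 for all causes, malignant neoplasms, heart
  disease and cerebrovascular disease.
- PHN density: ln(PHN per 100k) = 8.54 − 0.48 ln(pop) + Normal(0, 0.30),
  which reproduces roughly 85 PHNs per 100k below the 10,000-population
  threshold versus roughly 40 above it (between-class Cohen's d > 1); other
  resources follow analogous ln-linear laws with signs matching the
  descriptive tables (physicians increase with size, clinics/hospitals/
  welfare facilities decrease per capita).
- Relative risks: theta = base x exp(beta'x + phi + eps + delta*t) with
  base ~ Gamma(130, 130) per municipality (EBSMR SD near 9 points),
  an ICAR field (scale 0.05) sampled exactly by eigen-decomposition of the
  graph Laplacian restricted to the non-null eigenspace, heterogeneity
  Normal(0, 0.03) per municipality-period, secular decline delta = −0.08,
  and a default PHN effect of −0.05 per ln unit.  Risk is driven by the
  same count-derived covariate values an analyst observes (counts are
  rounded and floored at 1), so estimators face no hidden
  errors-in-variables.
- `center_covariates=True` (default) applies effects to covariates centered
  at baseline means, keeping the national mean risk at 1 so EBSMRs sit near
  100; `center_covariates=False` generates exactly from the no-intercept
  regression form and is the right setting for parameter-recovery studies,
  at the cost of a shifted mean risk.
- Deaths: o ~ Poisson(e * theta), e from the same indirect standardization
  used downstream, pooled over 5 years.
- Adjacency: rectangular grid by default (always connected); a random
  geometric graph with bridged components behind a switch.

What the generator does **not** emulate: real geography or municipal
mergers, migration, sub-national age structure, time-varying reference
rates, socioeconomic confounders, or correlation between resource levels
beyond their common dependence on population size.  Passing recovery tests
therefore certify the estimators against the stated statistical model, not
against administrative-data pathologies.

## Problem sizes in the validation suite

The test and acceptance runs scale the study down while keeping its
structure: moment-estimator recovery uses 2,000 strata; mixed-model Wald
coverage uses 200 panels of n = 1,600 with 47 prefectures; BYM recovery
uses 20 replicate panels of 200 municipalities on a grid with 4 chains of
500+500 draws; null calibration uses 400 municipalities for EBSMR means and
five 100-municipality replicates for the BYM; the full-pipeline
reproducibility run uses 48–300 municipalities.  These sizes were chosen as
the smallest at which the Monte-Carlo error of each check is comfortably
below its tolerance.

## Known limitations

- The HMC engine uses fixed jittered trajectory lengths, not dynamic
  termination; heavily confounded level effects mix at a few hundred
  effective draws per 2,000 kept draws.  R-hat flags any failure.
- The moment estimator's exact agreement with legacy EB tools cannot be
  verified against their (undocumented) internals; the formula above is the
  specification.
- Exactly two periods are supported throughout; longer panels would need a
  different differencing and time model.
- Part-time PHN counts are realistically sparse; in small synthetic panels
  the full/part-time model variant can be rank deficient and is then
  skipped with a logged warning.
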