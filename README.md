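# ebsmr

Small-area mortality analysis for two-period municipality panels: empirical
Bayes smoothing of standardized mortality ratios (SMRs), first-difference
linear mixed models linking mortality change to public-health-workforce
change, and Besag–York–Mollié (BYM) spatial Poisson regression with full
Bayesian inference — plus a calibrated synthetic-panel generator so the whole
pipeline is testable without access to government registry data.

It is written for epidemiologists and health-services researchers who study
questions of the form *"did municipalities that gained public health nurses
(PHNs) see a larger drop in mortality?"* on ecological panel data.

## The statistics

**EBSMR.** For municipality i, indirect standardization gives expected deaths
`e_i = years * Σ_a pop_ia * rate_a` under base-year national age-specific
rates; the raw SMR is `100·o_i/e_i`. With `o_i ~ Poisson(e_i θ_i)` and a
conjugate prior `θ_i ~ Gamma(α, ν)` moment-fitted per prefecture (Marshall's
precision-weighted estimator), the EBSMR is the posterior mean

    EBSMR_i = 100·(o_i + α)/(e_i + ν) = w·SMR_i + (1−w)·100·m,   w = e_i/(e_i+ν)

— small municipalities are shrunk toward their prefecture mean, large ones
keep their own signal.

**First-difference model.** Per municipality, ΔEBSMR (2015−2010) is regressed
without intercept on Δln(PHN per 100k), Δln(population) and changes of other
per-100k healthcare resources, with a prefecture random intercept, by maximum
likelihood. With two periods this estimator is numerically identical to the
fixed-effects (within) estimator. Per-100k denominators use the 2010
population throughout.

**BYM model.** Stacking both periods,
`o_j ~ Poisson(μ_j)`, `log μ_j = log e_j + x_j'β + φ_m(j) + ε_j`, with an
intrinsic-CAR spatial field φ over the municipality adjacency graph (shared
across periods), unstructured heterogeneity ε, a 0/1 time dummy, and
covariates scaled by 1/1000 for readable coefficients. Posteriors are sampled
with an adaptive HMC engine; quantile credible intervals, split-chain R-hat
and bulk ESS are reported per parameter. A variant splits the PHN covariate
into its 2010 baseline and the 2010→2015 log-change.

See `docs/methods.md` for estimators, priors, sampler design and generator
calibration, and `docs/data_dictionary.md` for every file schema.

## Worked example

```python
import ebsmr

cfg = ebsmr.default_config(n_municipalities=400, n_prefectures=10, seed=3,
                           true_beta={"ln_phn": -0.05})
panel, adjacency, rates, truth = ebsmr.generate_panel(cfg)
table = ebsmr.compute_ebsmr_table(panel, rates)          # EB-smoothed SMRs
resources = ebsmr.resource_table_from_panel(panel)

sub = table[(table.sex == "male") & (table.cause == "all_causes")]
rows = ebsmr.build_first_difference(sub, resources)      # one row per municipality
covs = ["d_ln_phn", "d_ln_pop", "d_physicians", "d_clinics",
        "d_hospitals", "d_welfare_facilities"]
fit = ebsmr.fit_lmm_ml(rows["dy"].to_numpy(), rows[covs].to_numpy(),
                       groups=rows["prefecture_id"].to_numpy(), names=covs)
print(fit.coef_table())
```

prints

```
           covariate    coef     se       z      p
            d_ln_phn -6.8876 1.6946 -4.0644 0.0000
            d_ln_pop 11.1763 8.4111  1.3288 0.1839
        d_physicians  0.0025 0.0027  0.9458 0.3443
           d_clinics  0.0053 0.0075  0.7001 0.4839
         d_hospitals  0.0226 0.1091  0.2075 0.8356
d_welfare_facilities  0.0177 0.0449  0.3938 0.6937
```

The `d_ln_phn` coefficient says municipalities whose PHN density grew by one
log unit saw their all-cause EBSMR fall by about 6.9 points more than others
(p < 0.001); the generator's truth of −0.05 on log relative risk corresponds
to roughly −5 EBSMR points, inside one standard error. The same panel feeds
the BYM sensitivity analysis (`examples/04_bym_spatial_model.py`) and the
full report pipeline (`examples/05_full_study.py`), and each
`examples/0*.py` script is a self-contained narrative of one capability.

A thin command line mirrors the pipeline:

```sh
ebsmr simulate --seed 1 --out data/
ebsmr run-all --seed 1 --out results/     # EBSMR + panel models + q-values + BYM
```

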