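"""BYM spatial Poisson regression of death counts on PHN density.

Counts are Poisson with log(mu) = log(e) + x'beta + phi + eps: an offset of
log expected deaths, fixed covariate effects (scaled by 1/1000 for
readability), an ICAR spatial field shared by the two periods, and
unstructured heterogeneity.  The posterior is sampled with adaptive HMC;
the PHN covariate is also split into baseline level and five-year change.
"""

import ebsmr
from ebsmr.pipeline import bym_observation_table

cfg = ebsmr.default_config(n_municipalities=150, n_prefectures=6, seed=4,
                           true_beta={"ln_phn": -0.05}, spatial_sd=0.1,
                           hetero_sd=0.05, center_covariates=False)
panel, edges, rates, truth = ebsmr.generate_panel(cfg)
table = ebsmr.compute_ebsmr_table(panel, rates)
resources = ebsmr.resource_table_from_panel(panel)

obs = bym_observation_table(table[(table.sex == "male")
                           & (table.cause == "all_causes")],
                     resources, ("2010", "2015"))
graph = ebsmr.AdjacencyGraph.from_edge_list(
    edges, sorted(panel["municipality_id"].unique()))

spec = ebsmr.make_bym_spec(obs, graph, chains=4, warmup=400, draws=400, seed=4)
fit = ebsmr.fit_bym(spec, graph)
print("PHN-level model (coefficients on the 1/1000 reporting scale):")
print(fit.summary().round(2).to_string(index=False))

split = ebsmr.split_phn_covariate(spec)
fit2 = ebsmr.fit_bym(split, graph)
print("\nbaseline + change model:")
print(fit2.summary().round(2).to_string(index=False))
print(f"\ntruth: beta_PHN = -0.05 per ln unit = -50 on the reporting scale")
# A negative ln_phn (or ln_phn_change) estimate whose 95% credible interval
# excludes 0 indicates municipalities with more (or growing) PHN density had
# fewer deaths than their age structure predicts; R-hat near 1 certifies the
# chains agree.
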