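"""Generate a synthetic municipality mortality panel and inspect its shape.

The generator mimics a national two-census-year panel: log-normal
populations, PHN density falling with population size, gamma-distributed
municipal relative risks, a spatial ICAR field, and a secular mortality
decline between 2010 and 2015.
"""

import ebsmr

cfg = ebsmr.default_config(n_municipalities=200, n_prefectures=8, seed=1)
panel, adjacency, rates, truth = ebsmr.generate_panel(cfg)

resources = ebsmr.resource_table_from_panel(panel)
base = resources[resources["period"] == "2010"]
phn_per100k = base["phn_total"] * 1e5 / base["population"]
small = base["population"] < 10_000

print(f"panel rows: {len(panel)} "
      f"({cfg.n_municipalities} municipalities x 2 sexes x 4 causes x 2 periods)")
print(f"adjacency edges: {len(adjacency)} (rectangular grid, connected)")
print(f"population mean (SD): {base['population'].mean():,.0f} "
      f"({base['population'].std():,.0f})")
print(f"PHN per 100k, municipalities <10k: {phn_per100k[small].mean():.1f}; "
      f">=10k: {phn_per100k[~small].mean():.1f}")
print(f"true log-risk effect of ln(PHN density): "
      f"{truth.true_beta.get('ln_phn', 0.0):+.3f}")
# Small municipalities carry several-fold more PHNs per capita, and every
# number above is reproducible bit-for-bit from the seed.
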