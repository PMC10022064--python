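"""End-to-end study orchestration: simulate/load -> EBSMR -> panel models -> BYM.

``run_study`` reproduces the full analysis layout on a municipality panel:
descriptive tables split at a population threshold, bivariate no-intercept
regressions of EBSMR change on PHN change, adjusted first-difference mixed
models (with and without the prefecture random effect, for the AIC
comparison), stratified refits by baseline population and baseline EBSMR,
Benjamini–Hochberg q-values across the cause-specific outcomes, and the two
BYM sensitivity variants (pooled PHN level; baseline + change split).  Every
table is plain delimited text and regenerable from the manifest (config +
seed) alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import panel as pm
from . import spatial
from . import synthetic
from .standardize import ReferenceRates, compute_ebsmr_table

logger = logging.getLogger(__name__)


@dataclass
class StudyConfig:
    """Configuration of one study run.

    Thresholds carry the analysis conventions: the small-municipality split
    at a baseline population of 10,000, the baseline-EBSMR split at 100, a
    0.05 significance level, q-values reported at the 0.10 level, and the
    1/1000 covariate scaling of the BYM reporting scale.
    """

    generator: synthetic.GeneratorConfig | None = None
    panel_path: str | None = None
    rates_path: str | None = None
    adjacency_path: str | None = None
    sexes: tuple[str, ...] = synthetic.SEXES
    causes: tuple[str, ...] = synthetic.CAUSES
    run_descriptives: bool = True
    run_bivariate: bool = True
    run_adjusted: bool = True
    run_stratified: bool = True
    run_bym: bool = True
    run_bym_split: bool = True
    pop_threshold: float = 10_000.0
    ebsmr_threshold: float = 100.0
    alpha: float = 0.05
    q_level: float = 0.10
    covariate_scale: float = spatial.DEFAULT_COVARIATE_SCALE
    years_per_period: int = 5
    bym_chains: int = 4
    bym_warmup: int = 500
    bym_draws: int = 500
    seed: int = 0
    output_dir: str | None = None

    def validate(self) -> None:
        if min(self.pop_threshold, self.ebsmr_threshold, self.alpha, self.q_level) <= 0:
            raise ValueError("thresholds must be positive")
        if not any([self.run_descriptives, self.run_bivariate, self.run_adjusted,
                    self.run_stratified, self.run_bym]):
            raise ValueError("at least one analysis variant must be selected")

    def manifest(self) -> dict:
        d = dataclasses.asdict(self)
        if self.generator is not None:
            d["generator"] = dataclasses.asdict(self.generator)
        blob = json.dumps(d, sort_keys=True, default=str)
        return {"config": d,
                "config_hash": hashlib.sha256(blob.encode()).hexdigest()[:16]}


@dataclass
class ReportBundle:
    descriptive: pd.DataFrame | None = None
    change: pd.DataFrame | None = None
    bivariate: pd.DataFrame | None = None
    adjusted: pd.DataFrame | None = None
    stratified: pd.DataFrame | None = None
    bym: pd.DataFrame | None = None
    qvalues: pd.DataFrame | None = None
    ebsmr: pd.DataFrame | None = None
    manifest: dict = field(default_factory=dict)
    partial: bool = False
    failed_stage: str | None = None

    def tables(self) -> dict[str, pd.DataFrame]:
        return {k: v for k, v in vars(self).items()
                if isinstance(v, pd.DataFrame)}

    def write(self, outdir: str | Path) -> None:
        out = Path(outdir)
        out.mkdir(parents=True, exist_ok=True)
        for name, df in self.tables().items():
            df.to_csv(out / f"{name}.tsv", sep="\t", index=False, float_format="%.10g")
        (out / "manifest.json").write_text(
            json.dumps(self.manifest, indent=1, sort_keys=True, default=str))
        with open(out / "report.txt", "w") as fh:
            for name, df in self.tables().items():
                fh.write(f"== {name} ==\n{df.to_string(index=False)}\n\n")


def filter_panel(panel: pd.DataFrame, flag_cols: list[str] | None = None) -> pd.DataFrame:
    """Drop rows with any active exclusion flag (columns ``exclude_*``)."""
    cols = flag_cols if flag_cols is not None else \
        [c for c in panel.columns if c.startswith("exclude_")]
    if not cols:
        return panel
    keep = np.ones(len(panel), dtype=bool)
    for c in cols:
        active = panel[c].astype(bool).to_numpy()
        logger.info("exclusion flag %s removes %d rows", c, int(active.sum()))
        keep &= ~active
    out = panel[keep].drop(columns=cols).reset_index(drop=True)
    if out.empty:
        logger.warning("all rows excluded by flags")
    return out


_DESC_RESOURCES = ["phn_total", "phn_full_time", "phn_part_time", "physicians",
                   "clinics", "hospitals", "welfare_facilities"]


def describe(
    ebsmr_table: pd.DataFrame,
    resource_table: pd.DataFrame,
    pop_threshold: float = 10_000.0,
    mode: str = "baseline",
    periods: tuple[str, str] = ("2010", "2015"),
) -> pd.DataFrame:
    """Descriptive table split at a baseline-population threshold.

    ``mode='baseline'`` summarizes period-0 levels; ``mode='change'``
    summarizes 2015-2010 changes.  Resource counts are reported per 100,000
    of the baseline population.  Cohen's d compares the small (< threshold)
    against the large (>= threshold) class.
    """
    p0, p1 = periods
    res0 = resource_table[resource_table["period"] == p0].set_index("municipality_id")
    base_pop = res0["population"]

    def _per100k(tab):
        tab = tab.set_index("municipality_id")
        out = pd.DataFrame(index=tab.index)
        for c in _DESC_RESOURCES:
            out[c + "_per100k"] = tab[c] * 1e5 / base_pop.reindex(tab.index)
        out["population"] = tab["population"]
        return out

    values: dict[str, pd.Series] = {}
    eb = ebsmr_table.pivot_table(index=["municipality_id"],
                                 columns=["sex", "cause", "period"], values="ebsmr")
    for (sex, cause, period) in eb.columns:
        if mode == "baseline" and period != p0:
            continue
        if mode == "baseline":
            values[f"ebsmr_{sex}_{cause}"] = eb[(sex, cause, period)]
    if mode == "change":
        for sex in ebsmr_table["sex"].unique():
            for cause in ebsmr_table["cause"].unique():
                values[f"ebsmr_{sex}_{cause}"] = \
                    eb[(sex, cause, p1)] - eb[(sex, cause, p0)]
        res1 = resource_table[resource_table["period"] == p1]
        delta = _per100k(res1) - _per100k(resource_table[resource_table["period"] == p0])
        for c in delta.columns:
            values[c] = delta[c]
    else:
        lv = _per100k(resource_table[resource_table["period"] == p0].reset_index())
        for c in lv.columns:
            values[c] = lv[c]

    small = base_pop < pop_threshold
    rows = []
    for name, series in values.items():
        s = series.reindex(base_pop.index).astype(float)
        a, b = s[small], s[~small]
        if a.size < 2 or b.size < 2:
            logger.warning("size class with <2 municipalities for %s", name)
            d = float("nan")
        else:
            d = pm.cohens_d(a.to_numpy(), b.to_numpy())
        rows.append({
            "variable": name,
            "mean_all": s.mean(), "sd_all": s.std(ddof=1),
            "mean_small": a.mean(), "sd_small": a.std(ddof=1) if a.size > 1 else float("nan"),
            "mean_large": b.mean(), "sd_large": b.std(ddof=1) if b.size > 1 else float("nan"),
            "n_small": int(a.size), "n_large": int(b.size),
            "cohens_d": d,
        })
    return pd.DataFrame(rows)


def _load_inputs(config: StudyConfig):
    if config.generator is not None:
        panel, edges, rates, truth = synthetic.generate_panel(config.generator)
        return panel, edges, rates, truth
    panel = pd.read_csv(config.panel_path, sep="\t", dtype={"period": str})
    edges = pd.read_csv(config.adjacency_path, sep="\t")
    rates = ReferenceRates(pd.read_csv(config.rates_path, sep="\t"))
    return panel, edges, rates, None


def bym_observation_table(ebsmr_sc: pd.DataFrame, resources: pd.DataFrame,
                   periods: tuple[str, str]) -> pd.DataFrame:
    p0, _ = periods
    res = resources.copy()
    base_pop = res[res["period"] == p0].set_index("municipality_id")["population"]
    res["base_pop"] = res["municipality_id"].map(base_pop)
    res["ln_phn"] = np.log(np.maximum(res["phn_total"], 0.5) * 1e5 / res["base_pop"])
    res["ln_pop"] = np.log(res["population"])
    for c, out in [("physicians", "physicians_per100k"), ("clinics", "clinics_per100k"),
                   ("hospitals", "hospitals_per100k"),
                   ("welfare_facilities", "welfare_per100k")]:
        res[out] = res[c] * 1e5 / res["base_pop"]
    obs = ebsmr_sc[["municipality_id", "period", "o", "e"]].merge(
        res, on=["municipality_id", "period"], how="inner")
    obs["time_dummy"] = (obs["period"] != p0).astype(float)
    return obs.sort_values(["period", "municipality_id"]).reset_index(drop=True)


def run_study(config: StudyConfig) -> ReportBundle:
    """Execute all selected stages; failures mark the bundle partial."""
    config.validate()
    bundle = ReportBundle(manifest=config.manifest())
    bundle.manifest["seed"] = config.seed

    stage = "inputs"
    try:
        panel, edges, rates, truth = _load_inputs(config)
        panel = filter_panel(panel)
        periods = tuple(sorted(panel["period"].unique()))
        resources = synthetic.resource_table_from_panel(panel)

        stage = "standardize"
        ebsmr = compute_ebsmr_table(panel, rates, years=config.years_per_period)
        bundle.ebsmr = ebsmr

        if config.run_descriptives:
            stage = "descriptives"
            bundle.descriptive = describe(ebsmr, resources, config.pop_threshold,
                                          mode="baseline", periods=periods)
            bundle.change = describe(ebsmr, resources, config.pop_threshold,
                                     mode="change", periods=periods)

        diffs: dict[tuple[str, str], pd.DataFrame] = {}
        stage = "first_difference"
        for sex in config.sexes:
            for cause in config.causes:
                sc = ebsmr[(ebsmr["sex"] == sex) & (ebsmr["cause"] == cause)]
                diffs[(sex, cause)] = pm.build_first_difference(
                    sc, resources, periods=periods)

        qval_records = []
        if config.run_bivariate:
            stage = "bivariate"
            rows = []
            for (sex, cause), d in diffs.items():
                splits = {"all": np.ones(len(d), dtype=bool),
                          "pop_below": d["baseline_pop"] < config.pop_threshold,
                          "pop_above": d["baseline_pop"] >= config.pop_threshold}
                for label, mask in splits.items():
                    sub = d[mask]
                    coef, p = pm.simple_regression_no_intercept(
                        sub["dy"].to_numpy(), sub["d_ln_phn"].to_numpy())
                    rows.append({"sex": sex, "cause": cause, "stratum": label,
                                 "n": len(sub), "coef": coef, "p": p})
                    qval_records.append(("bivariate", sex, label, cause, p))
            bundle.bivariate = pd.DataFrame(rows)

        if config.run_adjusted:
            stage = "adjusted"
            rows = []
            for (sex, cause), d in diffs.items():
                for variant, covs in pm.MODEL_VARIANTS.items():
                    y = d["dy"].to_numpy()
                    X = d[list(covs)].to_numpy()
                    try:
                        fit = pm.fit_lmm_ml(y, X, groups=d["prefecture_id"].to_numpy(),
                                            names=list(covs))
                    except pm.RankDeficiencyError as exc:
                        logger.warning("variant %s skipped for %s/%s: %s",
                                       variant, sex, cause, exc)
                        continue
                    fit_nore = pm.fit_lmm_ml(y, X, groups=None, names=list(covs))
                    for j, name in enumerate(fit.names):
                        rows.append({
                            "sex": sex, "cause": cause, "model": variant,
                            "covariate": name, "coef": fit.beta[j],
                            "se": fit.se[j], "p": fit.p[j],
                            "aic": fit.aic, "aic_no_random": fit_nore.aic,
                            "sigma2_u": fit.sigma2_u, "sigma2_e": fit.sigma2_e,
                            "n": fit.n, "converged": fit.converged,
                        })
                        if name == "d_ln_phn" and variant == "all_phn":
                            qval_records.append(("adjusted", sex, "all", cause, fit.p[j]))
                    vif_tab = pm.vif(X, names=list(covs))
                    logger.info("VIF range %s %s %s: %.2f-%.2f", sex, cause, variant,
                                vif_tab["vif"].min(), vif_tab["vif"].max())
            bundle.adjusted = pd.DataFrame(rows)

        if config.run_stratified:
            stage = "stratified"
            rows = []
            covs = pm.MODEL_VARIANTS["all_phn"]
            specs = [("baseline_pop", config.pop_threshold, "population"),
                     ("baseline_ebsmr", config.ebsmr_threshold, "ebsmr")]
            for (sex, cause), d in diffs.items():
                for field_name, threshold, label in specs:
                    fits = pm.stratified_fits(d, covs, field_name, threshold)
                    for stratum, fit in fits.items():
                        j = fit.names.index("d_ln_phn")
                        rows.append({
                            "sex": sex, "cause": cause,
                            "stratified_by": label, "stratum": stratum,
                            "n": fit.n, "coef": fit.beta[j], "se": fit.se[j],
                            "p": fit.p[j], "converged": fit.converged,
                        })
                        if label == "population":
                            qval_records.append(
                                (f"stratified_pop_{stratum}", sex, stratum, cause,
                                 fit.p[j]))
            bundle.stratified = pd.DataFrame(rows)

        if qval_records:
            stage = "qvalues"
            qdf = pd.DataFrame(qval_records,
                               columns=["analysis", "sex", "stratum", "cause", "p"])
            parts = []
            for (analysis, sex, stratum), grp in qdf.groupby(
                    ["analysis", "sex", "stratum"]):
                grp = grp.copy()
                grp["q"] = pm.bh_qvalues(grp["p"].to_numpy())
                parts.append(grp)
            q = pd.concat(parts, ignore_index=True)
            q["significant_q"] = q["q"] < config.q_level
            bundle.qvalues = q

        if config.run_bym:
            stage = "bym"
            munis = sorted(panel["municipality_id"].unique())
            graph = spatial.AdjacencyGraph.from_edge_list(edges, munis)
            rows = []
            for si, sex in enumerate(config.sexes):
                for ci, cause in enumerate(config.causes):
                    sc = ebsmr[(ebsmr["sex"] == sex) & (ebsmr["cause"] == cause)]
                    obs = bym_observation_table(sc, resources, periods)
                    sub_seed = (config.seed * 997 + si * 31 + ci * 7) % (2 ** 31 - 1)
                    spec = spatial.make_bym_spec(
                        obs, graph, covariate_scale=config.covariate_scale,
                        chains=config.bym_chains, warmup=config.bym_warmup,
                        draws=config.bym_draws, seed=sub_seed)
                    variants = {"phn_level": spec}
                    if config.run_bym_split:
                        variants["phn_baseline_change"] = spatial.split_phn_covariate(spec)
                    for vname, vspec in variants.items():
                        fit = spatial.fit_bym(vspec, graph)
                        summ = fit.summary()
                        summ.insert(0, "model", vname)
                        summ.insert(0, "cause", cause)
                        summ.insert(0, "sex", sex)
                        summ["converged"] = fit.converged
                        summ["seed"] = vspec.seed
                        rows.append(summ)
            bundle.bym = pd.concat(rows, ignore_index=True)
    except Exception:
        bundle.partial = True
        bundle.failed_stage = stage
        logger.exception("stage %r failed; bundle marked partial", stage)

    if config.output_dir:
        bundle.write(config.output_dir)
    return bundle
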