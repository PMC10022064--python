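"""Synthetic municipality mortality panels with known ground truth.

The generator emulates the statistical structure of a two-census-year Japanese
municipality panel: log-normally distributed populations, a shared national
age pyramid, public-health-nurse (PHN) density falling with population size,
gamma-distributed municipal relative risks, an intrinsic-CAR spatial field on
a connected adjacency graph, unstructured log-normal heterogeneity, and a
secular mortality decline between the two periods.  Observed deaths are
Poisson draws around indirectly standardized expectations, pooled over a
five-year window per period.

Every draw flows from one seed, and the ground-truth parameters (coefficients
on log relative risk, the spatial field, the per-municipality relative risks)
are returned alongside the tables so downstream estimators can be checked for
recovery.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .standardize import ReferenceRates

logger = logging.getLogger(__name__)

SEXES = ("male", "female")
CAUSES = ("all_causes", "malignant_neoplasms", "heart_disease", "cerebrovascular_disease")

# Five-year age groups 0-4 ... 85+ with a national pyramid shared by all
# municipalities (normalized in code).
AGE_GROUPS = tuple(
    [f"{a:02d}_{a + 4:02d}" for a in range(0, 85, 5)] + ["85_plus"]
)
_PYRAMID = np.array([
    0.042, 0.044, 0.047, 0.048, 0.051, 0.058, 0.064, 0.073, 0.064,
    0.060, 0.061, 0.068, 0.078, 0.066, 0.058, 0.047, 0.036, 0.035,
])
_PYRAMID = _PYRAMID / _PYRAMID.sum()
_AGE_MID = np.array([a + 2.5 for a in range(0, 85, 5)] + [90.0])

# Target crude death rates (per person-year) and cause shares used to anchor
# the Gompertz reference-rate schedule.
_CDR_TARGET = {"male": 0.0105, "female": 0.0085}
_CAUSE_SHARE = {
    "all_causes": 1.0,
    "malignant_neoplasms": 0.30,
    "heart_disease": 0.155,
    "cerebrovascular_disease": 0.10,
}
_GOMPERTZ_B = 0.095  # log-rate slope per year of age


class InvalidConfigError(ValueError):
    pass


@dataclass
class GeneratorConfig:
    """Parameters of the synthetic panel generator.

    Population sizes are log-normal on the natural scale
    (``pop_lognormal_mu``/``sigma`` are log-scale parameters, calibrated so the
    default sample mean/SD sit near 44,300 and 57,700).  PHN density follows
    ln(PHN per 100k) = phn_intercept - phn_slope * ln(population) + noise, so
    small municipalities are richer in PHNs per capita.  Municipal base
    relative risks are Gamma(prior_shape, prior_rate); ``prior_shape = inf``
    pins them at 1 exactly (null model).  ``true_beta`` maps covariate names
    (``ln_phn``, ``ln_pop``) to effects on the log relative risk; with
    ``center_covariates`` (the default) effects apply to covariates centered
    at their baseline means so the national average risk stays calibrated,
    while ``center_covariates=False`` generates exactly from the no-intercept
    regression form (parameter-recovery setups).
    """

    n_municipalities: int = 1601
    n_prefectures: int = 47
    n_age_groups: int = len(AGE_GROUPS)
    periods: tuple[str, str] = ("2010", "2015")
    pop_lognormal_mu: float = 10.2026
    pop_lognormal_sigma: float = 0.9961
    phn_intercept: float = 8.54
    phn_slope: float = 0.48
    phn_noise_sd: float = 0.30
    true_beta: dict[str, float] = field(default_factory=lambda: {"ln_phn": -0.05})
    prior_shape: float = 130.0
    prior_rate: float = 130.0
    spatial_sd: float = 0.05
    hetero_sd: float = 0.03
    time_effect: float = -0.08
    years_per_period: int = 5
    adjacency: str = "grid"  # or "geometric"
    center_covariates: bool = True
    age_tilt_sd: float = 0.0  # optional prefecture-level old-age tilt (log scale)
    seed: int = 0

    def validate(self) -> None:
        if self.n_municipalities < 1 or self.n_prefectures < 1 or self.n_age_groups < 1:
            raise InvalidConfigError("counts must be >= 1")
        if self.pop_lognormal_sigma <= 0:
            raise InvalidConfigError("population sigma must be positive")
        if min(self.phn_noise_sd, self.spatial_sd, self.hetero_sd, self.age_tilt_sd) < 0:
            raise InvalidConfigError("standard deviations must be non-negative")
        if self.phn_slope < 0:
            raise InvalidConfigError("phn_slope must be >= 0")
        if self.prior_rate <= 0 or self.prior_shape <= 0:
            raise InvalidConfigError("gamma prior parameters must be positive")
        if len(self.periods) != 2:
            raise InvalidConfigError("exactly two periods expected")
        if self.adjacency not in ("grid", "geometric"):
            raise InvalidConfigError(f"unknown adjacency kind {self.adjacency!r}")


@dataclass
class SyntheticTruth:
    """Ground truth behind one generated panel."""

    true_beta: dict[str, float]
    theta: pd.DataFrame          # municipality_id, period, theta
    phi: np.ndarray              # per-municipality spatial effect
    prior_shape: float
    prior_rate: float
    time_effect: float
    covariate_means: dict[str, float]

    def to_json(self) -> str:
        payload = {
            "true_beta": self.true_beta,
            "prior_shape": self.prior_shape,
            "prior_rate": self.prior_rate,
            "time_effect": self.time_effect,
            "covariate_means": self.covariate_means,
            "phi": [float(v) for v in self.phi],
            "theta": self.theta.to_dict(orient="list"),
        }
        return json.dumps(payload, indent=1, sort_keys=True)


def default_config(**overrides) -> GeneratorConfig:
    """A config calibrated to the magnitudes of a national municipal panel."""
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


def make_adjacency(n: int, kind: str = "grid", rng: np.random.Generator | None = None) -> nx.Graph:
    """Connected adjacency graph over ``n`` nodes labelled 0..n-1.

    ``grid`` lays municipalities on a near-square lattice (always connected);
    ``geometric`` draws a random geometric graph and bridges any disconnected
    components (logged) so the ICAR field stays well defined.
    """
    if kind == "grid":
        ncol = int(math.ceil(math.sqrt(n)))
        nrow = int(math.ceil(n / ncol))
        g = nx.grid_2d_graph(nrow, ncol)
        nodes = sorted(g.nodes())[:n]
        g = g.subgraph(nodes).copy()
        mapping = {node: i for i, node in enumerate(sorted(g.nodes()))}
        return nx.relabel_nodes(g, mapping)
    rng = rng or np.random.default_rng(0)
    pos = {i: rng.uniform(0, 1, size=2) for i in range(n)}
    radius = 1.8 / math.sqrt(n)
    g = nx.random_geometric_graph(n, radius, pos=pos)
    comps = list(nx.connected_components(g))
    if len(comps) > 1:
        logger.warning("geometric adjacency had %d components; bridging", len(comps))
        anchor = sorted(comps[0])[0]
        for comp in comps[1:]:
            g.add_edge(anchor, sorted(comp)[0])
    return g


def sample_icar_field(graph: nx.Graph, sd: float, rng: np.random.Generator) -> np.ndarray:
    """Draw from the intrinsic-CAR density with scale ``sd``.

    The ICAR precision is the graph Laplacian L = D - W scaled by 1/sd^2; the
    draw lives in the subspace orthogonal to the per-component constant
    vectors, i.e. sums to zero within each connected component.  Sampling is
    by eigen-decomposition of L restricted to its positive eigenvalues.
    """
    n = graph.number_of_nodes()
    if sd == 0:
        return np.zeros(n)
    lap = nx.laplacian_matrix(graph, nodelist=range(n)).toarray().astype(float)
    evals, evecs = np.linalg.eigh(lap)
    ncomp = nx.number_connected_components(graph)
    pos = slice(ncomp, None)  # eigenvalues sorted ascending; first ncomp are null
    z = rng.standard_normal(n - ncomp)
    phi = evecs[:, pos] @ (z / np.sqrt(evals[pos]))
    return sd * phi


def _reference_rate_schedule() -> pd.DataFrame:
    """Gompertz age-specific reference rates anchored to the crude death rates."""
    rows = []
    shape = np.exp(_GOMPERTZ_B * _AGE_MID)
    for sex in SEXES:
        a = _CDR_TARGET[sex] / float(_PYRAMID @ shape)
        for cause in CAUSES:
            rates = a * _CAUSE_SHARE[cause] * shape
            for ag, r in zip(AGE_GROUPS, rates):
                rows.append({"age_group": ag, "sex": sex, "cause": cause, "rate": r})
    return pd.DataFrame(rows)


def _ln_linear_resource(rng, ln_pop, intercept, slope, noise_sd):
    """Per-100k resource level: ln(level) = intercept + slope*ln(pop) + noise."""
    return np.exp(intercept + slope * ln_pop + rng.normal(0.0, noise_sd, size=ln_pop.size))


def generate_panel(config: GeneratorConfig):
    """Generate (panel, adjacency edge list, reference rates, truth).

    The panel is long format: one row per municipality x sex x cause x period
    with observed deaths ``o``, age-group populations ``pop_<group>``, and the
    municipality's resource counts and population repeated across rows.
    Adjacency is a two-column edge DataFrame over municipality ids.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_municipalities
    muni_ids = np.array([f"M{i:04d}" for i in range(n)])

    # prefectures: contiguous blocks along grid order => spatially coherent
    pref_of = np.minimum(
        (np.arange(n) * config.n_prefectures) // n, config.n_prefectures - 1)
    pref_ids = np.array([f"P{p:02d}" for p in pref_of])

    graph = make_adjacency(n, config.adjacency, rng)
    edges = pd.DataFrame(
        sorted((min(u, v), max(u, v)) for u, v in graph.edges()),
        columns=["node_a", "node_b"])
    edges["municipality_a"] = muni_ids[edges["node_a"]]
    edges["municipality_b"] = muni_ids[edges["node_b"]]
    edges = edges[["municipality_a", "municipality_b"]]

    # populations and their five-year evolution (slight national decline)
    pop10 = np.exp(rng.normal(config.pop_lognormal_mu, config.pop_lognormal_sigma, n))
    pop10 = np.maximum(pop10, 200.0).round()
    pop15 = np.maximum(pop10 * np.exp(rng.normal(-0.02, 0.03, n)), 150.0).round()
    pops = {config.periods[0]: pop10, config.periods[1]: pop15}
    ln_pop10 = np.log(pop10)

    # age structure: shared pyramid, optional prefecture-level old-age tilt
    pyramid = np.tile(_PYRAMID, (n, 1))
    if config.age_tilt_sd > 0:
        tilt = rng.normal(0.0, config.age_tilt_sd, config.n_prefectures)[pref_of]
        pyramid = pyramid * np.exp(np.outer(tilt, (_AGE_MID - _AGE_MID.mean()) / 50.0))
        pyramid = pyramid / pyramid.sum(axis=1, keepdims=True)

    # PHN density declines with population size
    ln_phn10 = (config.phn_intercept - config.phn_slope * ln_pop10
                + rng.normal(0.0, config.phn_noise_sd, n))
    phn10_per100k = np.exp(ln_phn10)
    phn15_per100k = phn10_per100k * np.exp(rng.normal(0.05, 0.15, n))
    part_frac = rng.beta(1.0, 30.0, size=n)

    def _counts(per100k, pop):
        return np.maximum(np.rint(per100k * pop / 1e5), 0.0)

    resources = {}
    for period, pop in pops.items():
        phn_per = phn10_per100k if period == config.periods[0] else phn15_per100k
        phn_count = np.maximum(_counts(phn_per, pop10), 1.0)  # denominator fixed at baseline pop
        part = np.rint(phn_count * part_frac)
        drift = 1.0 if period == config.periods[0] else np.exp(rng.normal(0.02, 0.05, n))
        resources[period] = pd.DataFrame({
            "municipality_id": muni_ids,
            "prefecture_id": pref_ids,
            "period": period,
            "population": pop,
            "phn_total": phn_count,
            "phn_full_time": phn_count - part,
            "phn_part_time": part,
            "physicians": _counts(_ln_linear_resource(rng, ln_pop10, -1.2, 0.55, 0.45) * drift, pop10),
            "clinics": _counts(_ln_linear_resource(rng, ln_pop10, 5.0, -0.08, 0.35) * drift, pop10),
            "hospitals": np.maximum(_counts(_ln_linear_resource(rng, ln_pop10, 3.4, -0.15, 0.25) * drift, pop10), 1.0),
            "welfare_facilities": _counts(_ln_linear_resource(rng, ln_pop10, 6.3, -0.45, 0.40) * drift, pop10),
        })
    resource_table = pd.concat(resources.values(), ignore_index=True)

    # ground-truth relative risks
    if math.isinf(config.prior_shape):
        base = np.ones(n)
    else:
        base = rng.gamma(config.prior_shape, 1.0 / config.prior_rate, n)
    phi = sample_icar_field(graph, config.spatial_sd, rng)
    # period-specific covariates (centered at their baseline means) so the
    # effect of a *change* in PHN density is identified downstream; risk is
    # driven by the same count-derived densities an analyst would observe,
    # not the latent pre-rounding values
    covariates = {
        period: {
            "ln_phn": np.log(resources[period]["phn_total"].to_numpy() * 1e5 / pop10),
            "ln_pop": np.log(pops[period]),
        }
        for period in config.periods
    }
    if config.center_covariates:
        cov_means = {k: float(v.mean())
                     for k, v in covariates[config.periods[0]].items()}
    else:
        # risk follows the no-intercept form exactly (recovery setups)
        cov_means = {k: 0.0 for k in covariates[config.periods[0]]}
    lin = {}
    for period in config.periods:
        acc = np.zeros(n)
        for name, beta in config.true_beta.items():
            if name not in cov_means:
                raise InvalidConfigError(f"true_beta names unknown covariate {name!r}")
            acc += beta * (covariates[period][name] - cov_means[name])
        lin[period] = acc

    rates = ReferenceRates(_reference_rate_schedule(), base_year=config.periods[0])
    rate_vectors = {
        (sex, cause): rates.vector(sex, cause, list(AGE_GROUPS))
        for sex in SEXES for cause in CAUSES
    }

    panel_rows = []
    theta_rows = []
    for t, period in enumerate(config.periods):
        eps = rng.normal(0.0, config.hetero_sd, n) if config.hetero_sd > 0 else np.zeros(n)
        theta = base * np.exp(lin[period] + phi + eps + config.time_effect * t)
        theta_rows.append(pd.DataFrame(
            {"municipality_id": muni_ids, "period": period, "theta": theta}))
        pop_age = pops[period][:, None] * pyramid  # age-group person counts
        pop_cols = {f"pop_{ag}": pop_age[:, j].round(1) for j, ag in enumerate(AGE_GROUPS)}
        for sex in SEXES:
            for cause in CAUSES:
                e = config.years_per_period * pop_age @ rate_vectors[(sex, cause)]
                o = rng.poisson(e * theta)
                df = pd.DataFrame({
                    "municipality_id": muni_ids,
                    "prefecture_id": pref_ids,
                    "sex": sex, "cause": cause, "period": period,
                    "o": o,
                })
                for k, v in pop_cols.items():
                    df[k] = v
                panel_rows.append(df)
    panel = pd.concat(panel_rows, ignore_index=True)
    panel = panel.merge(
        resource_table.drop(columns="prefecture_id"),
        on=["municipality_id", "period"], how="left")

    truth = SyntheticTruth(
        true_beta=dict(config.true_beta),
        theta=pd.concat(theta_rows, ignore_index=True),
        phi=phi,
        prior_shape=config.prior_shape,
        prior_rate=config.prior_rate,
        time_effect=config.time_effect,
        covariate_means=cov_means,
    )
    return panel, edges, rates, truth


def resource_table_from_panel(panel: pd.DataFrame) -> pd.DataFrame:
    """Unique municipality x period resource/population rows of a panel."""
    cols = ["municipality_id", "prefecture_id", "period", "population",
            "phn_total", "phn_full_time", "phn_part_time",
            "physicians", "clinics", "hospitals", "welfare_facilities"]
    present = [c for c in cols if c in panel.columns]
    return panel[present].drop_duplicates(
        subset=["municipality_id", "period"]).reset_index(drop=True)
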