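"""Besag–York–Mollié spatial Poisson regression by full Bayesian inference.

Observed death counts are modelled as

    o_j ~ Poisson(mu_j),   log(mu_j) = log(e_j) + x_j' beta + phi_{m(j)} + eps_j

where e_j is the indirectly standardized expected count (an offset), phi is an
intrinsic conditional autoregressive (ICAR) field over the municipality
adjacency graph — shared by the two periods of a municipality — and eps is
unstructured log-normal heterogeneity per observation.  Sampling uses the
package's adaptive HMC engine on the centered parameterization (the expected
counts are large, so the likelihood pins the latent effects), with the
regression block preconditioned by a dense Cholesky factor; the ICAR field is
identified by exact mean-centering per connected component inside the model
(a soft sum-to-zero penalty is available behind a flag).

Covariates other than the time dummy are scaled (by 1/1000 by default) before
fitting so coefficient magnitudes are readable; summaries report both the
scaled ("reporting") and the natural scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd

from ._hmc import sample_hmc

logger = logging.getLogger(__name__)


class DimensionError(ValueError):
    pass


@dataclass
class AdjacencyGraph:
    """Undirected municipality adjacency for the ICAR prior."""

    nodes: list
    edges: np.ndarray            # (n_edges, 2) int node indices, i < j
    degrees: np.ndarray
    components: np.ndarray       # component label per node

    @classmethod
    def from_edge_list(cls, edge_df: pd.DataFrame, nodes: list) -> "AdjacencyGraph":
        """Build from a two-column edge list whose ids match ``nodes``."""
        index = {n: i for i, n in enumerate(nodes)}
        a = edge_df.iloc[:, 0].map(index)
        b = edge_df.iloc[:, 1].map(index)
        if a.isna().any() or b.isna().any():
            raise DimensionError("edge list references unknown node ids")
        pairs = {(min(i, j), max(i, j)) for i, j in zip(a.astype(int), b.astype(int))
                 if i != j}
        edges = np.array(sorted(pairs), dtype=int).reshape(-1, 2)
        g = nx.Graph()
        g.add_nodes_from(range(len(nodes)))
        g.add_edges_from(edges)
        degrees = np.array([g.degree(i) for i in range(len(nodes))])
        if (degrees == 0).any():
            logger.warning("%d isolated nodes: no spatial smoothing for them",
                           int((degrees == 0).sum()))
        comp = np.empty(len(nodes), dtype=int)
        n_comp = 0
        for cc in nx.connected_components(g):
            for i in cc:
                comp[i] = n_comp
            n_comp += 1
        if n_comp > 1:
            logger.warning("adjacency has %d components; per-component "
                           "sum-to-zero applied", n_comp)
        return cls(nodes=list(nodes), edges=edges, degrees=degrees, components=comp)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_components(self) -> int:
        return int(self.components.max()) + 1


def icar_log_density(phi: np.ndarray, graph: AdjacencyGraph, tau: float = 1.0) -> float:
    """Pairwise-difference ICAR log density, up to its additive constant:
    -(tau/2) * sum over unique edges of (phi_i - phi_j)^2."""
    phi = np.asarray(phi, dtype=float)
    if phi.size != graph.n_nodes:
        raise DimensionError("phi length does not match graph")
    if tau <= 0:
        raise ValueError("tau must be positive")
    d = phi[graph.edges[:, 0]] - phi[graph.edges[:, 1]]
    return float(-0.5 * tau * np.sum(d * d))


@dataclass
class BYMModelSpec:
    """Data and settings for one BYM fit.

    ``X`` holds the covariates *already scaled for reporting*; ``scale``
    records, per column, the factor applied (estimates divided by it recover
    the natural scale).  ``muni_index`` maps each observation row to its
    node in the adjacency graph; the ICAR field is shared across periods.
    """

    o: np.ndarray
    log_e: np.ndarray
    X: np.ndarray
    names: list[str]
    muni_index: np.ndarray
    scale: np.ndarray
    beta_prior_sd: float = 5.0   # per natural covariate unit
    scale_prior_sd: float = 1.0
    chains: int = 4
    warmup: int = 500
    draws: int = 500
    seed: int = 0
    target_accept: float = 0.9
    n_leapfrog: tuple[int, int] = (24, 56)
    constraint: str = "project"  # or "soft"
    include_spatial: bool = True
    include_hetero: bool = True
    prior_only: bool = False     # sample the prior (likelihood switched off)

    def __post_init__(self) -> None:
        self.o = np.asarray(self.o, dtype=float)
        self.log_e = np.asarray(self.log_e, dtype=float)
        self.X = np.atleast_2d(np.asarray(self.X, dtype=float))
        self.muni_index = np.asarray(self.muni_index, dtype=int)
        if not np.isfinite(self.log_e).all():
            raise ValueError("offset log(e) must be finite (all e > 0)")
        if (self.o < 0).any():
            raise ValueError("counts must be non-negative")
        n = self.o.size
        if self.X.shape[0] != n or self.log_e.size != n or self.muni_index.size != n:
            raise DimensionError("o, log_e, X and muni_index must align")


#: Default readability scaling for covariates other than the time dummy.
DEFAULT_COVARIATE_SCALE = 1.0 / 1000.0


def make_bym_spec(
    obs: pd.DataFrame,
    graph: AdjacencyGraph,
    covariates: tuple[str, ...] = ("ln_phn", "ln_pop", "physicians_per100k",
                                   "clinics_per100k", "hospitals_per100k",
                                   "welfare_per100k"),
    time_col: str = "time_dummy",
    covariate_scale: float = DEFAULT_COVARIATE_SCALE,
    **settings,
) -> BYMModelSpec:
    """Assemble a model spec from a stacked observation table.

    ``obs`` has one row per municipality x period with columns ``o``, ``e``,
    the covariates, the 0/1 time dummy, and ``municipality_id`` matching the
    graph's nodes.  Every covariate except the time dummy is multiplied by
    ``covariate_scale``.
    """
    index = {n: i for i, n in enumerate(graph.nodes)}
    muni_index = obs["municipality_id"].map(index)
    if muni_index.isna().any():
        raise DimensionError("observation table references nodes absent from graph")
    names = list(covariates) + [time_col]
    scale = np.array([covariate_scale] * len(covariates) + [1.0])
    X = obs[names].to_numpy(dtype=float) * scale
    e = obs["e"].to_numpy(dtype=float)
    if (e <= 0).any():
        raise ValueError("expected counts must be positive for the offset")
    return BYMModelSpec(
        o=obs["o"].to_numpy(dtype=float), log_e=np.log(e), X=X, names=names,
        muni_index=muni_index.to_numpy(dtype=int), scale=scale, **settings)


def split_phn_covariate(spec: BYMModelSpec, phn_col: str = "ln_phn") -> BYMModelSpec:
    """Split the PHN covariate into baseline and change columns.

    The baseline column carries the period-0 value of ln(PHN per 100k) on
    both of a municipality's rows; the change column is the difference of
    logs, switched on by the time dummy (0 at baseline, the log-change at
    follow-up).  Scaling of the original column is inherited by both.
    """
    if phn_col not in spec.names:
        raise ValueError(f"{phn_col!r} not among covariates")
    j = spec.names.index(phn_col)
    t = spec.X[:, -1]  # time dummy is always last
    if not set(np.unique(t)) <= {0.0, 1.0}:
        raise ValueError("time dummy must be 0/1")
    phn = spec.X[:, j]
    baseline = np.empty_like(phn)
    base_by_muni: dict[int, float] = {}
    for row in np.flatnonzero(t == 0):
        base_by_muni[spec.muni_index[row]] = phn[row]
    missing = set(spec.muni_index) - set(base_by_muni)
    if missing:
        raise ValueError("municipalities lack a baseline-period row")
    for row in range(phn.size):
        baseline[row] = base_by_muni[spec.muni_index[row]]
    change = (phn - baseline) * t  # nonzero only at follow-up
    X = spec.X.copy()
    X[:, j] = baseline
    X = np.insert(X, j + 1, change, axis=1)
    names = list(spec.names)
    names[j] = phn_col + "_baseline"
    names.insert(j + 1, phn_col + "_change")
    scale = np.insert(spec.scale.copy(), j + 1, spec.scale[j])
    return replace(spec, X=X, names=names, scale=scale)


@dataclass
class BYMFit:
    """Posterior draws and summaries of one BYM fit."""

    spec: BYMModelSpec
    beta: np.ndarray             # (chains, draws, p) on the reporting scale
    phi: np.ndarray              # (chains, draws, n_nodes), sum-to-zero/component
    sigma_phi: np.ndarray        # (chains, draws)
    sigma_eps: np.ndarray
    accept_rate: np.ndarray
    divergences: np.ndarray

    @property
    def converged(self) -> bool:
        return bool(self.summary()["rhat"].max() < 1.05)

    def beta_draws(self, name: str, natural_scale: bool = False) -> np.ndarray:
        j = self.spec.names.index(name)
        d = self.beta[:, :, j].ravel()
        return d * self.spec.scale[j] if natural_scale else d

    def summary(self, level: float = 0.95) -> pd.DataFrame:
        rows = []
        for j, name in enumerate(self.spec.names):
            d = self.beta[:, :, j]
            lo, hi = quantile_ci(d.ravel(), level)
            rows.append({
                "parameter": name, "mean": d.mean(),
                "ci_low": lo, "ci_high": hi,
                "mean_natural": d.mean() * self.spec.scale[j],
                "rhat": rhat(d), "ess": effective_sample_size(d),
            })
        for name, d in [("sigma_phi", self.sigma_phi), ("sigma_eps", self.sigma_eps)]:
            if d is None:
                continue
            lo, hi = quantile_ci(d.ravel(), level)
            rows.append({"parameter": name, "mean": d.mean(), "ci_low": lo,
                         "ci_high": hi, "mean_natural": d.mean(),
                         "rhat": rhat(d), "ess": effective_sample_size(d)})
        return pd.DataFrame(rows)


def _bym_logp_grad_factory(spec: BYMModelSpec, graph: AdjacencyGraph,
                           beta_chol: np.ndarray | None = None):
    """Analytic log posterior and gradient over the packed parameter vector.

    Layout: u (p) | phi (n_nodes) | eps (n_obs) | log s_phi | log s_eps,
    with phi and eps on their natural (centered) scale: the expected counts
    here are large, so the likelihood pins the latent effects and the
    centered parameterization keeps the scale parameters well conditioned.
    The improper ICAR density contributes -(n - n_components) log(s_phi) as
    its normalizing power of the precision.

    ``beta_chol`` is an optional dense preconditioner: the regression block
    is sampled as u with beta = beta_chol @ u, which removes the strong
    collinearity between covariates (e.g. PHN density vs population) that a
    diagonal mass matrix cannot capture.
    """
    o, log_e, X = spec.o, spec.log_e, spec.X
    idx = spec.muni_index
    p = X.shape[1]
    n_nodes = graph.n_nodes if spec.include_spatial else 0
    n_obs = o.size if spec.include_hetero else 0
    ea, eb = (graph.edges[:, 0], graph.edges[:, 1]) if spec.include_spatial else (None, None)
    comp = graph.components if spec.include_spatial else None
    n_comp = graph.n_components if spec.include_spatial else 0
    comp_sizes = np.bincount(comp, minlength=n_comp).astype(float) if spec.include_spatial else None
    icar_rank = n_nodes - n_comp
    # beta_prior_sd is interpreted per *natural* covariate unit; convert to
    # the reporting scale so the readability scaling cannot tighten the prior
    bsd2 = (spec.beta_prior_sd / spec.scale) ** 2
    ssd2 = spec.scale_prior_sd ** 2
    soft_sd = 0.001  # per-component soft sum-to-zero: mean(phi) ~ N(0, soft_sd)

    C = beta_chol if beta_chol is not None else np.eye(p)

    def unpack(q):
        k = 0
        beta = C @ q[k:k + p]; k += p
        phi = q[k:k + n_nodes]; k += n_nodes
        eps = q[k:k + n_obs]; k += n_obs
        rest = q[k:]
        return beta, phi, eps, rest

    def logp_grad(q):
        # divergent warmup trajectories can push the log-scales far out;
        # clip so exp() stays finite (the move is rejected anyway)
        q = np.clip(q, -1e6, 1e6)
        if n_scales := (int(spec.include_spatial) + int(spec.include_hetero)):
            q[-n_scales:] = np.clip(q[-n_scales:], -40.0, 40.0)
        beta, phi, eps, rest = unpack(q)
        grad = np.empty_like(q)
        k = 0
        eta = log_e + X @ beta
        if spec.include_spatial:
            s_phi = np.exp(rest[0])
            if spec.constraint == "project":
                cm = np.bincount(comp, weights=phi, minlength=n_comp) / comp_sizes
                phi_c = phi - cm[comp]
            else:
                phi_c = phi
            eta = eta + phi_c[idx]
        if spec.include_hetero:
            s_eps = np.exp(rest[-1])
            eta = eta + eps
        eta = np.clip(eta, -500, 500)
        if spec.prior_only:
            lp, g = 0.0, np.zeros_like(o)
        else:
            mu = np.exp(eta)
            lp = float(o @ eta - mu.sum())
            g = o - mu  # dlp/deta

        lp += float(-0.5 * np.sum(beta * beta / bsd2))
        grad[k:k + p] = C.T @ (X.T @ g - beta / bsd2)
        k += p

        if spec.include_spatial:
            tau = 1.0 / (s_phi * s_phi)
            gm = np.bincount(idx, weights=g, minlength=n_nodes)
            if spec.constraint == "project":
                gm_cm = np.bincount(comp, weights=gm, minlength=n_comp) / comp_sizes
                gm = gm - gm_cm[comp]
            d = phi[ea] - phi[eb]
            ssq = float(np.sum(d * d))
            lp += -0.5 * tau * ssq - icar_rank * rest[0]
            # L phi accumulated from edge differences
            lap = np.bincount(ea, weights=d, minlength=n_nodes) \
                - np.bincount(eb, weights=d, minlength=n_nodes)
            g_phi = gm - tau * lap
            comp_means = np.bincount(comp, weights=phi, minlength=n_comp) / comp_sizes
            if spec.constraint == "soft":
                lp += float(-0.5 * np.sum((comp_means / soft_sd) ** 2))
                g_phi -= (comp_means / (soft_sd ** 2 * comp_sizes))[comp]
            else:
                # the projected-out mean direction is unidentified; pin it
                lp += float(-0.5 * np.sum(comp_means ** 2))
                g_phi -= (comp_means / comp_sizes)[comp]
            grad[k:k + n_nodes] = g_phi
            k += n_nodes

        if spec.include_hetero:
            ive = 1.0 / (s_eps * s_eps)
            lp += float(-0.5 * ive * (eps @ eps)) - n_obs * rest[-1]
            grad[k:k + n_obs] = g - ive * eps
            k += n_obs

        if spec.include_spatial:
            lp += -0.5 * s_phi ** 2 / ssd2 + rest[0]
            grad[k] = tau * ssq - icar_rank - s_phi ** 2 / ssd2 + 1.0
            k += 1
        if spec.include_hetero:
            lp += -0.5 * s_eps ** 2 / ssd2 + rest[-1]
            grad[k] = ive * float(eps @ eps) - n_obs - s_eps ** 2 / ssd2 + 1.0
        return lp, grad

    dim = p + n_nodes + n_obs + int(spec.include_spatial) + int(spec.include_hetero)
    return logp_grad, dim, unpack


def fit_bym(spec: BYMModelSpec, graph: AdjacencyGraph) -> BYMFit:
    """Sample the BYM posterior; see the module docstring for the model."""
    p = spec.X.shape[1]
    n_scales = int(spec.include_spatial) + int(spec.include_hetero)
    # penalized Poisson IRLS: mode of beta with random effects at zero
    beta0 = np.zeros(p)
    prior_prec = (spec.scale / spec.beta_prior_sd) ** 2
    for _ in range(0 if spec.prior_only else 50):
        mu = np.exp(np.clip(spec.log_e + spec.X @ beta0, -500, 500))
        grad_b = spec.X.T @ (spec.o - mu) - beta0 * prior_prec
        hess = spec.X.T @ (mu[:, None] * spec.X) + np.diag(prior_prec)
        step = np.linalg.solve(hess, grad_b)
        beta0 = beta0 + step
        if np.max(np.abs(step)) < 1e-10:
            break
    mu0 = np.exp(np.clip(spec.log_e + spec.X @ beta0, -500, 500))
    # dense preconditioner for the regression block, from the Hessian with
    # Poisson information discounted by the heterogeneity term
    s0 = 0.1
    w = 1.0 / (1.0 + s0 ** 2 * mu0)
    if spec.prior_only:
        mu0 = np.zeros_like(mu0)
        w = np.ones_like(w)
    hess_w = spec.X.T @ ((mu0 * w)[:, None] * spec.X) + np.diag(prior_prec)
    chol_h = np.linalg.cholesky(hess_w)
    beta_chol = np.linalg.inv(chol_h).T  # C C' = inv(hess_w)

    logp_grad, dim, unpack = _bym_logp_grad_factory(spec, graph, beta_chol)
    init = np.zeros(dim)
    if n_scales:
        init[-n_scales:] = np.log(s0)
    init[:p] = chol_h.T @ beta0  # u such that C u = beta0
    # place the Poisson residuals into the heterogeneity term so chains start
    # near the posterior bulk, shrunk toward 0 by the initial scale
    if spec.include_hetero:
        resid = np.log((spec.o + 0.5) / (mu0 + 0.5))
        shrink = s0 ** 2 * mu0 / (1.0 + s0 ** 2 * mu0)
        n_nodes_used = graph.n_nodes if spec.include_spatial else 0
        init[p + n_nodes_used:p + n_nodes_used + spec.o.size] = shrink * resid
        # jitter latent effects on their local posterior scale
    jitter = np.full(dim, 0.05)
    jitter[:p] = 1.0  # u is whitened
    if spec.include_hetero:
        jitter[p + (graph.n_nodes if spec.include_spatial else 0):dim - n_scales] = \
            0.5 / np.sqrt(1.0 + mu0)
    if n_scales:
        jitter[-n_scales:] = 0.2
    draws, stats = sample_hmc(
        logp_grad, init, n_warmup=spec.warmup, n_draws=spec.draws,
        n_chains=spec.chains, seed=spec.seed, target_accept=spec.target_accept,
        n_leapfrog=spec.n_leapfrog, init_jitter=jitter)
    if stats.divergences.sum() > 0:
        logger.warning("%d divergent trajectories", int(stats.divergences.sum()))

    beta = draws[:, :, :p] @ beta_chol.T
    n_nodes = graph.n_nodes
    if spec.include_spatial:
        phi_raw = draws[:, :, p:p + n_nodes]
        comp = graph.components
        # report phi centered per component (exact sum-to-zero)
        phi = np.empty_like(phi_raw)
        for c in range(graph.n_components):
            mask = comp == c
            mean_c = phi_raw[..., mask].mean(axis=-1, keepdims=True)
            phi[..., mask] = phi_raw[..., mask] - mean_c
        sigma_phi = np.exp(draws[:, :, -1 - int(spec.include_hetero)])
    else:
        phi = np.zeros((spec.chains, spec.draws, n_nodes))
        sigma_phi = np.zeros((spec.chains, spec.draws))
    if spec.include_hetero:
        sigma_eps = np.exp(draws[:, :, -1])
    else:
        sigma_eps = np.zeros((spec.chains, spec.draws))

    fit = BYMFit(spec=spec, beta=beta, phi=phi, sigma_phi=sigma_phi,
                 sigma_eps=sigma_eps, accept_rate=stats.accept_rate,
                 divergences=stats.divergences)
    if not fit.converged:
        logger.warning("BYM fit flagged non-converged (max R-hat %.3f)",
                       fit.summary()["rhat"].max())
    return fit


def quantile_ci(draws: np.ndarray, level: float = 0.95) -> tuple[float, float]:
    """Equal-tailed credible interval from empirical quantiles.

    Uses the linear-interpolation quantile convention; ``level=1`` returns
    the sample range.
    """
    draws = np.asarray(draws, dtype=float).ravel()
    if draws.size < 100:
        raise ValueError("need at least 100 draws for a quantile interval")
    if not 0 < level <= 1:
        raise ValueError("level must lie in (0, 1]")
    a = (1.0 - level) / 2.0
    lo, hi = np.quantile(draws, [a, 1.0 - a])
    return float(lo), float(hi)


def rhat(chain_draws: np.ndarray) -> float:
    """Split-chain potential scale reduction factor.

    ``chain_draws`` is (chains, draws); each chain is split in half, and the
    classic between/within variance ratio sqrt(((n-1)/n W + B/n) / W) is
    returned.
    """
    x = np.asarray(chain_draws, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 chains of equal length")
    half = x.shape[1] // 2
    if half < 2:
        raise ValueError("chains too short to split")
    splits = np.concatenate([x[:, :half], x[:, half:2 * half]], axis=0)
    m, n = splits.shape
    means = splits.mean(axis=1)
    w = splits.var(axis=1, ddof=1).mean()
    b = n * means.var(ddof=1)
    if w == 0:
        return 1.0
    var_plus = (n - 1) / n * w + b / n
    return float(np.sqrt(var_plus / w))


def effective_sample_size(chain_draws: np.ndarray) -> float:
    """Bulk effective sample size via arviz."""
    import arviz as az

    return float(az.ess(az.convert_to_dataset(np.asarray(chain_draws)))["x"].values)
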