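"""First-difference panel analysis of EBSMR change against workforce change.

The outcome is the between-period change in a municipality's EBSMR; the key
regressor is the change in log PHN density (per 100,000 of the *baseline*
population, so the denominator is held fixed).  With two periods the
first-difference estimator coincides with the within (fixed-effects)
estimator, and a prefecture random intercept absorbs prefecture-level secular
trends.  Fitting is by maximum likelihood with no intercept — a change model
has no level — using the closed-form profile likelihood of the single
random-intercept model.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

RESOURCE_DIFF_COLS = ("physicians", "clinics", "hospitals", "welfare_facilities")

ADJUSTERS = ("d_ln_pop", "d_physicians", "d_clinics", "d_hospitals", "d_welfare_facilities")
MODEL_VARIANTS = {
    "all_phn": ("d_ln_phn",) + ADJUSTERS,
    "full_part_phn": ("d_ln_phn_full", "d_ln_phn_part") + ADJUSTERS,
}


class RankDeficiencyError(ValueError):
    pass


class UnsupportedDesignError(ValueError):
    pass


@dataclass
class MixedModelFit:
    """ML fit of y = X beta + u_group + e with no intercept.

    ``sigma2_u`` is the prefecture random-intercept variance (0 when the
    random effect is excluded or estimated at the boundary); AIC counts the
    fixed effects plus both variance components (one for a plain OLS fit).
    """

    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    p: np.ndarray
    sigma2_u: float
    sigma2_e: float
    loglik: float
    aic: float
    n: int
    converged: bool
    random_effect: bool

    def coef_table(self) -> pd.DataFrame:
        return pd.DataFrame({
            "covariate": self.names, "coef": self.beta, "se": self.se,
            "z": self.z, "p": self.p,
        })


def build_first_difference(
    ebsmr_table: pd.DataFrame,
    resource_table: pd.DataFrame,
    periods: tuple[str, str] = ("2010", "2015"),
    zero_phn: str = "error",
) -> pd.DataFrame:
    """One differenced row per municipality x sex x cause.

    Log differences for PHN density and population; plain differences for the
    other per-100k resources.  Per-100k denominators use the baseline-period
    population for both periods so that workforce change is not confounded
    with population change.  A PHN count of zero in either period raises by
    default; ``zero_phn='offset'`` instead adds the smallest positive
    observed count (logged).
    """
    p0, p1 = periods
    res = resource_table.copy()
    base_pop = res[res["period"] == p0].set_index("municipality_id")["population"]
    res["base_pop"] = res["municipality_id"].map(base_pop)

    phn_cols = {"phn_total": "ln_phn", "phn_full_time": "ln_phn_full",
                "phn_part_time": "ln_phn_part"}
    for raw, out in phn_cols.items():
        if raw not in res.columns:
            continue
        counts = res[raw].to_numpy(dtype=float)
        if (counts <= 0).any():
            bad = res.loc[counts <= 0, "municipality_id"].unique()
            if zero_phn == "error" and raw == "phn_total":
                raise ValueError(
                    f"zero PHN count in municipalities {list(bad[:5])}; "
                    "pass zero_phn='offset' to apply a continuity correction")
            positive = counts[counts > 0]
            offset = positive.min() if positive.size else 1.0
            logger.warning("%s has %d zero counts; continuity offset %g added",
                           raw, int((counts <= 0).sum()), offset)
            counts = counts + offset
        res[out] = np.log(counts * 1e5 / res["base_pop"].to_numpy())
    res["ln_pop"] = np.log(res["population"])
    for c in RESOURCE_DIFF_COLS:
        res[c + "_per100k"] = res[c] * 1e5 / res["base_pop"]

    wide = res.set_index(["municipality_id", "period"])
    complete = set(res.loc[res["period"] == p0, "municipality_id"]) & \
        set(res.loc[res["period"] == p1, "municipality_id"])

    eb = ebsmr_table.pivot_table(index=["municipality_id", "sex", "cause"],
                                 columns="period", values="ebsmr").reset_index()
    eb = eb[eb["municipality_id"].isin(complete)].dropna(subset=list(periods))

    rows = eb.rename(columns={p0: "baseline_ebsmr"}).copy()
    rows["dy"] = eb[p1] - eb[p0]
    for out in ["ln_phn", "ln_phn_full", "ln_phn_part", "ln_pop"]:
        if out not in res.columns:
            continue
        v0 = wide.loc[[(m, p0) for m in rows["municipality_id"]], out].to_numpy()
        v1 = wide.loc[[(m, p1) for m in rows["municipality_id"]], out].to_numpy()
        rows["d_" + out] = v1 - v0
    for c in RESOURCE_DIFF_COLS:
        v0 = wide.loc[[(m, p0) for m in rows["municipality_id"]], c + "_per100k"].to_numpy()
        v1 = wide.loc[[(m, p1) for m in rows["municipality_id"]], c + "_per100k"].to_numpy()
        rows["d_" + c] = v1 - v0
    rows["baseline_pop"] = rows["municipality_id"].map(base_pop)
    rows["prefecture_id"] = rows["municipality_id"].map(
        res[res["period"] == p0].set_index("municipality_id")["prefecture_id"])
    diff_cols = [c for c in rows.columns if c.startswith("d")]
    if not np.isfinite(rows[diff_cols].to_numpy(dtype=float)).all():
        raise ValueError("non-finite differences encountered")
    return rows.drop(columns=[p1]).reset_index(drop=True)


def _profile_terms(y, X, idx, n_groups, lam):
    """GLS pieces for V0 = I + lam * Z Z' via Sherman-Morrison per group."""
    ng = np.bincount(idx, minlength=n_groups).astype(float)
    c = lam / (1.0 + lam * ng)  # per-group correction weight
    Sx = np.zeros((n_groups, X.shape[1]))
    np.add.at(Sx, idx, X)
    Sy = np.bincount(idx, weights=y, minlength=n_groups)
    A = X.T @ X - (Sx * c[:, None]).T @ Sx
    b = X.T @ y - Sx.T @ (c * Sy)
    return ng, c, Sx, Sy, A, b


def _profile_nll(lam, y, X, idx, n_groups):
    n = y.size
    ng, c, Sx, Sy, A, b = _profile_terms(y, X, idx, n_groups, lam)
    try:
        beta = np.linalg.solve(A, b)
    except np.linalg.LinAlgError:
        return np.inf, None, None
    r = y - X @ beta
    Sr = np.bincount(idx, weights=r, minlength=n_groups)
    rss = float(r @ r - Sr @ (c * Sr))
    rss = max(rss, 1e-290)
    sigma2_e = rss / n
    logdet = float(np.sum(np.log1p(lam * ng)))
    nll = 0.5 * (n * np.log(2 * np.pi * sigma2_e) + logdet + n)
    return nll, beta, sigma2_e


def fit_lmm_ml(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray | None = None,
    names: list[str] | None = None,
    use_t: bool = False,
) -> MixedModelFit:
    """No-intercept linear model by ML, optionally with a group random intercept.

    The variance ratio lambda = sigma2_u / sigma2_e is profiled out of the
    marginal Gaussian likelihood (Sherman–Morrison per group), maximized over
    [0, inf) so that lambda = 0 reduces the fit exactly to ordinary least
    squares.  Wald tests use a normal reference by default (``use_t`` switches
    to a t with n - p degrees of freedom).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        X = X.T
    n, p = X.shape
    if n <= p:
        raise RankDeficiencyError("more columns than observations")
    if np.linalg.matrix_rank(X) < p:
        raise RankDeficiencyError("design matrix is rank deficient")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]

    random_effect = groups is not None
    if random_effect:
        codes, _ = pd.factorize(np.asarray(groups))
        n_groups = int(codes.max()) + 1
    else:
        codes, n_groups = np.zeros(n, dtype=int), 1

    if random_effect and n_groups > 1:
        obj = lambda u: _profile_nll(np.exp(u), y, X, codes, n_groups)[0]
        grid = np.linspace(-12, 6, 37)
        best_u = grid[int(np.argmin([obj(u) for u in grid]))]
        opt = optimize.minimize_scalar(
            obj, bounds=(best_u - 1.5, best_u + 1.5), method="bounded",
            options={"xatol": 1e-10})
        lam = float(np.exp(opt.x))
        nll0, _, _ = _profile_nll(0.0, y, X, codes, n_groups)
        nll_hat, _, _ = _profile_nll(lam, y, X, codes, n_groups)
        if nll0 <= nll_hat + 1e-10:
            lam = 0.0
        converged = bool(opt.success) or lam == 0.0
    else:
        lam, converged = 0.0, True

    nll, beta, sigma2_e = _profile_nll(lam, y, X, codes, n_groups)
    if sigma2_e < 1e-280:
        logger.warning("residual variance numerically zero; fit is degenerate")
    _, _, _, _, A, _ = _profile_terms(y, X, codes, n_groups, lam)
    cov = sigma2_e * np.linalg.inv(A)
    se = np.sqrt(np.diag(cov))
    z = beta / se
    if use_t:
        pvals = 2 * stats.t.sf(np.abs(z), df=n - p)
    else:
        pvals = 2 * stats.norm.sf(np.abs(z))
    k_var = 2 if random_effect else 1
    loglik = -nll
    return MixedModelFit(
        names=names, beta=beta, se=se, z=z, p=pvals,
        sigma2_u=lam * sigma2_e, sigma2_e=sigma2_e,
        loglik=loglik, aic=-2 * loglik + 2 * (p + k_var),
        n=n, converged=converged, random_effect=random_effect,
    )


@dataclass
class FDFEReport:
    beta_fd: np.ndarray
    beta_fe: np.ndarray
    max_abs_diff: float


def first_difference_equals_fixed_effects(
    y: np.ndarray, X: np.ndarray, municipality: np.ndarray, period: np.ndarray
) -> FDFEReport:
    """Check the numerical identity of the FD and within estimators.

    ``y``/``X`` are stacked over municipality x period (exactly two periods).
    The first-difference estimator regresses between-period changes on
    changes; the fixed-effects (within) estimator demeans within municipality.
    With two periods both solve the same normal equations.
    """
    period = np.asarray(period)
    uniq = np.unique(period)
    if uniq.size != 2:
        raise UnsupportedDesignError("exactly two periods required")
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    muni = np.asarray(municipality)
    order0 = np.flatnonzero(period == uniq[0])
    order1 = np.flatnonzero(period == uniq[1])
    m0 = {m: i for m, i in zip(muni[order0], order0)}
    m1 = {m: i for m, i in zip(muni[order1], order1)}
    common = [m for m in muni[order0] if m in m1]
    i0 = np.array([m0[m] for m in common])
    i1 = np.array([m1[m] for m in common])

    dX = X[i1] - X[i0]
    dy = y[i1] - y[i0]
    if np.linalg.matrix_rank(dX) < dX.shape[1]:
        raise RankDeficiencyError("differenced design is rank deficient")
    beta_fd, *_ = np.linalg.lstsq(dX, dy, rcond=None)

    keep = np.concatenate([i0, i1])
    codes, _ = pd.factorize(muni[keep])
    Xw = X[keep] - pd.DataFrame(X[keep]).groupby(codes).transform("mean").to_numpy()
    yw = y[keep] - pd.Series(y[keep]).groupby(codes).transform("mean").to_numpy()
    if np.linalg.matrix_rank(Xw) < Xw.shape[1]:
        raise RankDeficiencyError("within-demeaned design is rank deficient")
    beta_fe, *_ = np.linalg.lstsq(Xw, yw, rcond=None)
    return FDFEReport(beta_fd=beta_fd, beta_fe=beta_fe,
                      max_abs_diff=float(np.max(np.abs(beta_fd - beta_fe))))


def simple_regression_no_intercept(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    """Slope and two-sided p-value of y = b*x with no intercept.

    b = sum(xy)/sum(x^2); the t statistic uses n - 1 residual degrees of
    freedom (one slope, no intercept).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    sxx = float(x @ x)
    if sxx == 0:
        raise ValueError("x is identically zero")
    b = float(x @ y) / sxx
    resid = y - b * x
    df = y.size - 1
    s2 = float(resid @ resid) / df
    se = np.sqrt(s2 / sxx)
    if se == 0:
        return b, 0.0 if b != 0 else 1.0
    p = 2 * stats.t.sf(abs(b / se), df=df)
    return b, float(p)


def vif(X: np.ndarray, names: list[str] | None = None) -> pd.DataFrame:
    """Variance inflation factors: 1/(1 - R^2_j) with an intercept in each
    auxiliary regression.  Exact collinearity is flagged with infinite VIF."""
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if p < 2:
        raise ValueError("VIF needs at least two columns")
    names = list(names) if names is not None else [f"x{j}" for j in range(p)]
    out = []
    for j in range(p):
        others = np.column_stack([np.ones(n), np.delete(X, j, axis=1)])
        target = X[:, j]
        coef, *_ = np.linalg.lstsq(others, target, rcond=None)
        resid = target - others @ coef
        tss = float(np.sum((target - target.mean()) ** 2))
        rss = float(resid @ resid)
        if tss == 0 or rss / max(tss, 1e-300) < 1e-12:
            out.append(np.inf)
        else:
            out.append(1.0 / (rss / tss))
    return pd.DataFrame({"covariate": names, "vif": out})


def bh_qvalues(pvals: np.ndarray) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, returned in input order."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    """Standardized mean difference with the pooled standard deviation.

    Returns NaN (with a warning) when the pooled SD is zero.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("both groups need at least 2 values")
    na, nb = a.size, b.size
    pooled = np.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1))
                     / (na + nb - 2))
    if pooled == 0:
        logger.warning("zero pooled SD: Cohen's d undefined")
        return float("nan")
    return float((a.mean() - b.mean()) / pooled)


def stratified_fits(
    rows: pd.DataFrame,
    covariates: tuple[str, ...],
    baseline_field: str,
    threshold: float,
    outcome: str = "dy",
    group_field: str = "prefecture_id",
) -> dict[str, MixedModelFit]:
    """Independent mixed-model fits below/above a baseline threshold.

    Strata follow the convention "below" = baseline < threshold,
    "above" = baseline >= threshold.  Empty strata are skipped with a
    warning; a stratum whose random-intercept fit does not converge is refit
    without the random effect (logged).
    """
    out: dict[str, MixedModelFit] = {}
    masks = {"below": rows[baseline_field] < threshold,
             "above": rows[baseline_field] >= threshold}
    for label, mask in masks.items():
        sub = rows[mask]
        if sub.empty:
            logger.warning("stratum %s (%s %s %g) is empty; skipped",
                           label, baseline_field, "<" if label == "below" else ">=",
                           threshold)
            continue
        y = sub[outcome].to_numpy()
        X = sub[list(covariates)].to_numpy()
        try:
            fit = fit_lmm_ml(y, X, groups=sub[group_field].to_numpy(),
                             names=list(covariates))
        except RankDeficiencyError as exc:
            logger.warning("stratum %s skipped: %s", label, exc)
            continue
        if not fit.converged:
            logger.warning("stratum %s mixed fit did not converge; OLS fallback", label)
            fit = fit_lmm_ml(y, X, groups=None, names=list(covariates))
        out[label] = fit
    return out
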