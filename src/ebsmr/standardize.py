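"""Indirect age standardization and empirical Bayes SMR smoothing.

The standardized mortality ratio (SMR) of a small area is o/e, the observed
death count divided by the count expected when national age-specific rates are
applied to the area's age-structured population.  For small municipalities the
raw SMR is dominated by Poisson noise, so the area-level relative risk theta is
given a conjugate gamma prior fitted per prefecture by precision-weighted
moment matching (Marshall's estimator), and the posterior mean

    E[theta | o] = (o + alpha) / (e + nu)

is reported, scaled so that the reference population sits at 100 (EBSMR).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: EBSMRs are reported relative to the base-year national value of 100.
SMR_SCALE = 100.0

#: Smallest prefecture group for which a local prior is moment-fitted;
#: smaller groups fall back to the pooled national prior.
MIN_GROUP_SIZE = 5


class SchemaError(ValueError):
    """Input table does not match the expected schema (e.g. age groups differ)."""


class InsufficientDataError(ValueError):
    """Too few strata to moment-fit a gamma prior."""


@dataclass(frozen=True)
class ReferenceRates:
    """Age-specific reference mortality rates (per person-year).

    ``table`` has columns ``age_group``, ``sex``, ``cause``, ``rate``.
    The same base-year rates are applied to every period so that SMRs
    remain comparable over time.
    """

    table: pd.DataFrame
    base_year: str = "2010"

    def __post_init__(self) -> None:
        required = {"age_group", "sex", "cause", "rate"}
        missing = required - set(self.table.columns)
        if missing:
            raise SchemaError(f"reference rate table lacks columns {sorted(missing)}")
        if (self.table["rate"] < 0).any():
            raise ValueError("reference rates must be non-negative")

    def vector(self, sex: str, cause: str, age_groups: list[str]) -> np.ndarray:
        """Rates for one sex x cause, ordered to match ``age_groups``."""
        sub = self.table[(self.table["sex"] == sex) & (self.table["cause"] == cause)]
        rates = sub.set_index("age_group")["rate"]
        missing = [a for a in age_groups if a not in rates.index]
        if missing:
            raise SchemaError(
                f"reference rates for sex={sex}, cause={cause} lack age groups {missing}"
            )
        return rates.reindex(age_groups).to_numpy(dtype=float)


@dataclass(frozen=True)
class MortalityStratum:
    """One municipality x sex x cause x period cell of the panel."""

    municipality_id: str
    prefecture_id: str
    sex: str
    cause: str
    period: str
    o: int
    e: float

    def __post_init__(self) -> None:
        if self.o < 0:
            raise ValueError("observed deaths must be non-negative")


@dataclass(frozen=True)
class GammaPrior:
    """Moment-estimated Gamma(shape, rate) prior on the relative risk.

    ``degenerate`` marks groups whose moment variance came out non-positive;
    those shrink completely to the group mean ``m``.
    """

    shape: float
    rate: float
    m: float
    group: str = ""
    degenerate: bool = False

    def __post_init__(self) -> None:
        if not self.degenerate and (self.shape <= 0 or self.rate <= 0):
            raise ValueError("non-degenerate prior needs shape > 0 and rate > 0")
        if self.m <= 0:
            raise ValueError("prior mean must be positive")


@dataclass(frozen=True)
class EBSMRResult:
    municipality_id: str
    sex: str
    cause: str
    period: str
    smr_raw: float
    ebsmr: float
    shrinkage_w: float


def expected_deaths(
    pop_by_age: np.ndarray | dict[str, float],
    rates: np.ndarray | dict[str, float],
    years: int = 1,
) -> float:
    """Expected deaths by indirect standardization: years * sum_a pop_a * rate_a.

    ``pop_by_age`` and ``rates`` are either aligned arrays or dicts keyed by age
    group; dict keys must coincide.  Death counts pooled over a multi-year
    window use ``years`` as the person-time multiplier.
    """
    if years < 1:
        raise ValueError("years must be >= 1")
    if isinstance(pop_by_age, dict) != isinstance(rates, dict):
        raise SchemaError("pop_by_age and rates must both be dicts or both arrays")
    if isinstance(pop_by_age, dict):
        if set(pop_by_age) != set(rates):
            raise SchemaError("age groups of population and rates do not match")
        keys = sorted(pop_by_age)
        pop = np.array([pop_by_age[k] for k in keys], dtype=float)
        rate = np.array([rates[k] for k in keys], dtype=float)
    else:
        pop = np.asarray(pop_by_age, dtype=float)
        rate = np.asarray(rates, dtype=float)
        if pop.shape != rate.shape:
            raise SchemaError("age groups of population and rates do not match")
    if (pop < 0).any():
        raise ValueError("population counts must be non-negative")
    if pop.sum() == 0:
        logger.warning("all-zero population: expected deaths is 0")
        return 0.0
    return float(years * np.dot(pop, rate))


def raw_smr(o: float, e: float) -> float:
    """Raw standardized mortality ratio 100 * o / e."""
    if e <= 0:
        raise ValueError("expected deaths must be positive for an SMR")
    if o < 0:
        raise ValueError("observed deaths must be non-negative")
    return SMR_SCALE * o / e


def fit_gamma_prior_moments(
    o: np.ndarray, e: np.ndarray, group: str = ""
) -> GammaPrior:
    """Marshall's precision-weighted moment estimator of the gamma prior.

    With observed counts o_i and expected counts e_i over the areas of one
    group, the prior mean and variance are estimated as

        m = sum(o) / sum(e)
        v = sum_i e_i (o_i/e_i - m)^2 / sum(e)  -  m / ebar,   ebar = mean(e)

    and mapped to Gamma(shape = m^2/v, rate = m/v).  A non-positive v means
    the between-area spread is no larger than Poisson noise; the prior is then
    degenerate at m (complete shrinkage).
    """
    o = np.asarray(o, dtype=float)
    e = np.asarray(e, dtype=float)
    if o.shape != e.shape:
        raise SchemaError("o and e must have equal length")
    if o.size < 2:
        raise InsufficientDataError("need at least 2 strata to fit a prior")
    if (e <= 0).any():
        raise ValueError("all expected counts must be positive")
    if (o < 0).any():
        raise ValueError("observed counts must be non-negative")
    m = o.sum() / e.sum()
    ebar = e.mean()
    v = float(np.sum(e * (o / e - m) ** 2) / e.sum() - m / ebar)
    if v <= 0 or m <= 0:
        return GammaPrior(shape=0.0, rate=0.0, m=max(m, np.finfo(float).tiny),
                          group=group, degenerate=True)
    return GammaPrior(shape=m * m / v, rate=m / v, m=m, group=group)


def eb_posterior_smr(o: float, e: float, prior: GammaPrior,
                     municipality_id: str = "", sex: str = "", cause: str = "",
                     period: str = "") -> EBSMRResult:
    """Posterior-mean SMR under Poisson(o | e*theta), theta ~ Gamma(alpha, nu).

    Conjugacy gives theta | o ~ Gamma(alpha + o, nu + e), so the EBSMR is
    100*(o + alpha)/(e + nu) — equivalently a weighted average
    w*raw + (1-w)*100*m with shrinkage weight w = e/(e + nu).
    """
    if o < 0:
        raise ValueError("observed deaths must be non-negative")
    if e <= 0:
        raise ValueError("expected deaths must be positive")
    smr = raw_smr(o, e)
    if prior.degenerate:
        return EBSMRResult(municipality_id, sex, cause, period,
                           smr_raw=smr, ebsmr=SMR_SCALE * prior.m, shrinkage_w=0.0)
    w = e / (e + prior.rate)
    ebsmr = SMR_SCALE * (o + prior.shape) / (e + prior.rate)
    return EBSMRResult(municipality_id, sex, cause, period,
                       smr_raw=smr, ebsmr=ebsmr, shrinkage_w=w)


def compute_ebsmr_table(
    panel: pd.DataFrame,
    rates: ReferenceRates,
    years: int = 5,
    grouping: str = "prefecture_id",
    min_group_size: int = MIN_GROUP_SIZE,
) -> pd.DataFrame:
    """EBSMR for every municipality x sex x cause x period in a panel.

    ``panel`` is long-format with columns ``municipality_id``,
    ``prefecture_id``, ``sex``, ``cause``, ``period``, ``o`` and age-group
    population columns ``pop_<age_group>``.  Priors are moment-fitted within
    ``grouping`` x sex x cause x period; groups smaller than
    ``min_group_size`` fall back to the pooled national prior (logged).
    The same base-year ``rates`` apply to every period.
    """
    pop_cols = [c for c in panel.columns if c.startswith("pop_")]
    if not pop_cols:
        raise SchemaError("panel lacks age-group population columns 'pop_*'")
    age_groups = [c[len("pop_"):] for c in pop_cols]

    out_rows: list[dict] = []
    for (sex, cause, period), sub in panel.groupby(["sex", "cause", "period"], sort=True):
        rate_vec = rates.vector(sex, cause, age_groups)
        pops = sub[pop_cols].to_numpy(dtype=float)
        e = years * pops @ rate_vec
        o = sub["o"].to_numpy(dtype=float)
        keep = e > 0
        if not keep.all():
            logger.warning(
                "%d strata with e=0 dropped for sex=%s cause=%s period=%s",
                (~keep).sum(), sex, cause, period)
        sub = sub.loc[keep]
        o, e = o[keep], e[keep]
        national = fit_gamma_prior_moments(o, e, group=f"national|{sex}|{cause}|{period}")
        groups = sub[grouping].to_numpy()
        priors: dict = {}
        for g in pd.unique(groups):
            mask = groups == g
            if mask.sum() < min_group_size:
                logger.info("group %s too small (%d); national prior used", g, mask.sum())
                priors[g] = national
            else:
                priors[g] = fit_gamma_prior_moments(
                    o[mask], e[mask], group=f"{g}|{sex}|{cause}|{period}")
        for idx, (muni, pref, oi, ei) in enumerate(
                zip(sub["municipality_id"], sub[grouping], o, e)):
            pr = priors[pref]
            res = eb_posterior_smr(oi, ei, pr)
            out_rows.append({
                "municipality_id": muni,
                "prefecture_id": sub["prefecture_id"].iloc[idx],
                "sex": sex, "cause": cause, "period": period,
                "o": oi, "e": ei,
                "smr_raw": res.smr_raw, "ebsmr": res.ebsmr,
                "shrinkage_w": res.shrinkage_w,
                "prior_shape": pr.shape, "prior_rate": pr.rate,
                "degenerate": pr.degenerate,
            })
    return pd.DataFrame(out_rows)
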