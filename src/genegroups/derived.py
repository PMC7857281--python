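"""Posterior-derived quantities from the genetic-groups animal model.

Everything here operates on full posterior distributions, never on
per-individual posterior point estimates: moments and trends of posterior
modes or means of breeding values are biased and are deliberately not
offered. Each statistic is computed draw by draw (vectorised across draws)
so its own full posterior is returned.

The central identity is u_i = a_i + g * q_i: an individual's total additive
genetic value is its breeding value (deviation from its group mean) plus the
immigrant group-mean effect weighted by its immigrant genome fraction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .animal_model import PosteriorSamples
from .pedigree import GroupCoefficients


@dataclass
class TrendResult:
    """Posterior of an individual-level OLS slope of values on natal year."""

    slopes: np.ndarray          # (S,) latent units per year
    prob_positive: float

    def summary(self) -> dict[str, float]:
        from .animal_model import hpd_interval

        lo, hi = hpd_interval(self.slopes)
        return {
            "posterior_mean": float(self.slopes.mean()),
            "hpd_lower": lo,
            "hpd_upper": hi,
            "prob_positive": self.prob_positive,
        }


def total_values(samples: PosteriorSamples, gc: GroupCoefficients) -> np.ndarray:
    """u = a + g * q per draw, over all pedigree individuals. Shape (S, n_ped)."""
    q = np.array([gc.q[gc.index[i]] for i in samples.ped_ids])
    return samples.a + samples.g[:, None] * q[None, :]


def group_effect_values(samples: PosteriorSamples, gc: GroupCoefficients) -> np.ndarray:
    """The immigrant genetic effect g * q per draw and individual."""
    q = np.array([gc.q[gc.index[i]] for i in samples.ped_ids])
    return samples.g[:, None] * q[None, :]


def trend_slope(values: np.ndarray, cohorts: np.ndarray,
                subset: np.ndarray | None = None) -> TrendResult:
    """OLS slope of individual values on natal year, one slope per draw.

    `values` is (S, n) across draws; `cohorts` gives each individual's natal
    year; `subset` restricts to the focal phenotyped individuals (boolean
    mask or index array). Individuals are the regression units, so cohort
    sizes act as implicit weights.
    """
    values = np.atleast_2d(values)
    cohorts = np.asarray(cohorts, dtype=float)
    if subset is not None:
        values = values[:, subset]
        cohorts = cohorts[subset]
    if len(np.unique(cohorts)) < 2:
        raise ValueError("trend slope needs at least two distinct cohorts")
    x = cohorts - cohorts.mean()
    denom = float(x @ x)
    slopes = (values - values.mean(axis=1, keepdims=True)) @ x / denom
    return TrendResult(slopes=slopes, prob_positive=float((slopes > 0).mean()))


def cohort_moments(values: np.ndarray, cohorts: np.ndarray,
                   subset: np.ndarray | None = None) -> pd.DataFrame:
    """Population variance and moment skew of values within each cohort, per draw.

    Variance divides by n (population form); skew is the third central
    moment over variance^1.5 and is reported as NaN for cohorts smaller
    than 3. Returns a tidy frame (draw, cohort, n, var, skew).
    """
    values = np.atleast_2d(values)
    cohorts = np.asarray(cohorts, dtype=float)
    if subset is not None:
        values = values[:, subset]
        cohorts = cohorts[subset]
    frames = []
    S = values.shape[0]
    for year in np.unique(cohorts):
        cols = cohorts == year
        v = values[:, cols]
        n = int(cols.sum())
        mean = v.mean(axis=1, keepdims=True)
        dev = v - mean
        var = (dev**2).mean(axis=1)
        if n >= 3:
            with np.errstate(divide="ignore", invalid="ignore"):
                skew = (dev**3).mean(axis=1) / var**1.5
        else:
            skew = np.full(S, np.nan)
        frames.append(pd.DataFrame({
            "draw": np.arange(S), "cohort": year, "n": n,
            "var": var, "skew": skew,
        }))
    return pd.concat(frames, ignore_index=True)


def moment_contrasts(mom_u: pd.DataFrame, mom_a: pd.DataFrame) -> pd.DataFrame:
    """Pairwise-draw contrasts var_u - var_a and skew_u - skew_a per cohort."""
    merged = mom_u.merge(mom_a, on=["draw", "cohort"], suffixes=("_u", "_a"))
    merged["var_diff"] = merged["var_u"] - merged["var_a"]
    merged["skew_diff"] = merged["skew_u"] - merged["skew_a"]
    return merged[["draw", "cohort", "var_diff", "skew_diff"]]


def backtransform_change(samples: PosteriorSamples, focal: np.ndarray,
                         cohorts: np.ndarray, year_pair: tuple[float, float],
                         sex: str = "F",
                         covariates: dict[str, float] | None = None,
                         centers: dict[str, float] | None = None) -> np.ndarray:
    """Posterior change in survival probability between two cohort years.

    Per draw, the latent predictor is evaluated at each year of `year_pair`
    with the focal genetic component (`focal`: per-draw values such as a or
    g*q, shape (S, n)) at its cohort mean, and all other fixed effects at
    the supplied covariate setting (defaults: f and clutch date at 0 offset
    from their centred means, year at its centre). Brood/year random effects
    are set to zero, so these are conditional, not population-averaged,
    probabilities. Returns p(year2) - p(year1) per draw.
    """
    covariates = covariates or {}
    centers = centers or {}
    cohorts = np.asarray(cohorts, dtype=float)

    beta = {c: samples.beta[:, k] for k, c in enumerate(samples.beta_columns)}
    base = beta["intercept"].copy()
    base += beta["f"] * covariates.get("f", 0.0)
    base += beta["clutch_date"] * (
        covariates.get("clutch_date", centers.get("clutch_date", 0.0))
        - centers.get("clutch_date", 0.0))
    base += beta["year"] * (
        covariates.get("year", centers.get("year", 0.0))
        - centers.get("year", 0.0))
    if sex.upper().startswith("M"):
        base += beta["sex"]

    probs = []
    for year in year_pair:
        cols = cohorts == year
        if not cols.any():
            raise ValueError(f"no individuals in cohort {year}")
        probs.append(expit(base + focal[:, cols].mean(axis=1)))
    return probs[1] - probs[0]
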