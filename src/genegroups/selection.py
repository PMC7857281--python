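"""Cohort-wise standardized phenotypic selection gradients on juvenile survival.

The gradient in each cohort is the OLS slope of relative fitness (individual
reproductive success divided by the cohort mean) on juvenile survival
standardized to unit variance within the cohort. Because individuals that
do not survive to adulthood leave zero local offspring, these gradients are
positive whenever any survivor reproduces; their magnitude summarises the
strength of directional selection on survival.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

FITNESS_COLUMNS = ("id", "cohort", "survival", "reproductive_success")


def validate_fitness_table(ft: pd.DataFrame) -> pd.DataFrame:
    missing = set(FITNESS_COLUMNS) - set(ft.columns)
    if missing:
        raise ValueError(f"fitness table lacks columns: {sorted(missing)}")
    rs = ft["reproductive_success"].to_numpy(dtype=float)
    if (rs < 0).any():
        raise ValueError("reproductive success must be non-negative")
    bad = (ft["survival"].to_numpy(dtype=float) == 0) & (rs > 0)
    if bad.any():
        raise ValueError(
            "non-survivors with nonzero local reproductive success: "
            + ", ".join(ft.loc[bad, "id"].astype(str).head(5))
        )
    return ft


def selection_gradient(ft: pd.DataFrame, validate: bool = True) -> pd.DataFrame:
    """Per-cohort standardized selection gradient plus the grand mean.

    Cohorts with fewer than 2 individuals, zero survival variance, or zero
    mean reproductive success are skipped with a warning. Returns a frame
    with one row per usable cohort; the grand mean (unweighted across
    cohorts) is available via `grand_mean_gradient`.
    """
    if validate:
        ft = validate_fitness_table(ft)
    rows = []
    for cohort, grp in ft.groupby("cohort"):
        surv = grp["survival"].to_numpy(dtype=float)
        rs = grp["reproductive_success"].to_numpy(dtype=float)
        if len(grp) < 2 or np.ptp(surv) == 0:
            warnings.warn(f"cohort {cohort}: no survival variance; skipped")
            continue
        if rs.mean() == 0:
            warnings.warn(f"cohort {cohort}: zero mean fitness; skipped")
            continue
        w = rs / rs.mean()                      # relative fitness
        z = (surv - surv.mean()) / surv.std()   # unit-variance survival
        beta = float(np.mean((w - w.mean()) * (z - z.mean())) / np.var(z))
        rows.append({"cohort": cohort, "n": len(grp), "gradient": beta})
    return pd.DataFrame(rows)


def grand_mean_gradient(gradients: pd.DataFrame) -> float:
    """Unweighted mean of the per-cohort gradients."""
    if gradients.empty:
        raise ValueError("no usable cohorts")
    return float(gradients["gradient"].mean())
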