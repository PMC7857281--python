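"""Gene-dropping drift null for breeding-value trends.

An observed increase in mean breeding value across cohorts is evidence of
selection only if it exceeds what genetic drift can generate on the same
pedigree. The null here simulates neutral breeding values down the observed
pedigree: founder values (natives and immigrants alike) are drawn from
N(0, V_A) and each non-founder receives the parental average plus a
Mendelian-sampling deviation with variance V_A * (0.5 - 0.25(f_sire +
f_dam)), the inbreeding-corrected form that matches the relatedness matrix
used in fitting (an uncorrected 0.5 * V_A option is available). One neutral
replicate is generated per retained posterior draw, using that draw's V_A,
so the drift distribution of slopes is paired to the posterior.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .animal_model import PosteriorSamples
from .derived import trend_slope
from .pedigree import Pedigree, mendelian_variances


@dataclass
class DriftEnsemble:
    """Paired observed and gene-dropped trend slopes, one pair per draw."""

    observed_slopes: np.ndarray
    drift_slopes: np.ndarray
    seed: int

    @property
    def delta(self) -> np.ndarray:
        return self.observed_slopes - self.drift_slopes

    @property
    def prob_exceeds_drift(self) -> float:
        """Posterior probability that the observed trend exceeds drift."""
        return float((self.delta > 0).mean())

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "draw": np.arange(len(self.delta)),
            "observed_slope": self.observed_slopes,
            "drift_slope": self.drift_slopes,
            "diff": self.delta,
        })


def gene_drop(ped: Pedigree, v_a, seed=None,
              rng: np.random.Generator | None = None,
              inbreeding_corrected: bool = True) -> np.ndarray:
    """Simulate neutral breeding values down the pedigree.

    `v_a` may be a scalar (returns shape (n_ped,)) or a vector of S
    posterior draws (returns (S, n_ped), one independent replicate per
    draw). An unknown parent contributes as a fresh phantom native founder,
    which folds into the Mendelian term (variance 0.75 - 0.25 f_known).
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    v = np.atleast_1d(np.asarray(v_a, dtype=float))
    if (v <= 0).any():
        raise ValueError("V_A must be strictly positive")
    scalar = np.isscalar(v_a) or np.ndim(v_a) == 0
    S = len(v)
    n = len(ped)
    d = mendelian_variances(ped) if inbreeding_corrected else None
    sd_founder = np.sqrt(v)

    a = np.empty((S, n))
    sire, dam = ped.sire_idx, ped.dam_idx
    for k in range(n):
        s, m = sire[k], dam[k]
        if s < 0 and m < 0:
            a[:, k] = sd_founder * rng.standard_normal(S)
            continue
        mid = np.zeros(S)
        if s >= 0:
            mid += 0.5 * a[:, s]
        if m >= 0:
            mid += 0.5 * a[:, m]
        dk = d[k] if inbreeding_corrected else 0.5
        a[:, k] = mid + np.sqrt(v * dk) * rng.standard_normal(S)
    return a[0] if scalar else a


def drift_test(samples: PosteriorSamples, ped: Pedigree,
               cohorts: np.ndarray, subset: np.ndarray | None = None,
               seed: int = 0,
               inbreeding_corrected: bool = True) -> DriftEnsemble:
    """Compare the posterior breeding-value trend with its paired drift null.

    For each retained draw s, neutral values are gene-dropped with that
    draw's V_A and the trend slope is computed on the same focal subset as
    the observed slope; the proportion of positive paired differences is
    the posterior probability that the observed trend exceeds drift.
    """
    if list(samples.ped_ids) != list(ped.ids):
        raise ValueError("posterior samples and pedigree are indexed differently")
    observed = trend_slope(samples.a, cohorts, subset).slopes
    dropped = gene_drop(ped, samples.v_a, seed=seed,
                        inbreeding_corrected=inbreeding_corrected)
    drift_slopes = trend_slope(dropped, cohorts, subset).slopes
    return DriftEnsemble(observed_slopes=observed, drift_slopes=drift_slopes,
                         seed=seed)
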