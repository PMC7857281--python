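"""Fit the Bayesian genetic-groups animal model to a simulated study.

Simulates a reduced study (10 cohorts of ~60 chicks, every cohort
phenotyped), fits the logit-link animal model with Polya-Gamma Gibbs
sampling, and prints the posterior summary in the usual layout: variance
components and heritability on the latent scale, then fixed effects. The
coefficient on q is the immigrant genetic-group effect g - the difference
in mean additive genetic value between immigrant and native founders.
"""

from genegroups import (ChainConfig, build_design, fit, prune_to_phenotyped,
                        reduced_config, simulate_reliable)

res = simulate_reliable(reduced_config(seed=2), min_observations=450)
ped = prune_to_phenotyped(res.build_pedigree(), res.observations["id"])
design = build_design(res.observations, ped)

samples = fit(design, chain=ChainConfig(iterations=2000, burn_in=400, thin=2,
                                        seed=1))

print(samples.summary().round(3).to_string(index=False))
print("\ngenerative values: V_A 0.36, V_brood 0.19, V_year 1.11, g -2.36,")
print("f slope -8.92, year -0.06, clutch date -0.01, sex contrast 0.56")
print("lag-1 autocorrelation:",
      {k: round(v, 2) for k, v in samples.autocorr.items()})

# Posterior means land near the generative values given ~600 binary
# observations; intervals are wide because a single binary record per
# individual carries little information about latent-scale variances.
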