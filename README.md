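# genegroups

Quantitative genetics of migration–selection balance in wild pedigrees.

Small, isolated populations that receive occasional immigrants pose a
puzzle: a fitness component can carry real additive genetic variance and be
under strong, consistent directional selection, and yet show no
evolutionary change. One resolution is that gene flow supplies a steady
stream of alleles with low additive value for *local* fitness, so the local
selection response is cancelled by immigration. `genegroups` implements
the full analysis needed to expose this balance from pedigree and
life-history data for a binary fitness component (juvenile survival to
adulthood), together with a forward simulator of the island study design so
every stage can be validated against known truth.

## The model

Each individual's **total additive genetic value** for the trait is

&nbsp;&nbsp;&nbsp;&nbsp;*u*ᵢ = *a*ᵢ + *g·q*ᵢ

where *a*ᵢ is the breeding value (the individual's additive deviation from
its genetic-group mean), *q*ᵢ is the **immigrant genetic-group
coefficient** — the expected fraction of the genome descending from
immigrant founders, obtained by averaging parental values down the pedigree
— and *g* is the **genetic-group effect**, the difference in mean additive
value between immigrant and native founders (native mean fixed at zero).

Survival is analysed on the latent logit scale with a Bayesian
genetic-groups animal model:

&nbsp;&nbsp;&nbsp;&nbsp;logit P(survive) = **x**ᵢ′β + *a*ᵢ + brood + year + eᵢ

with fixed effects [intercept, *q*ᵢ, inbreeding *f*ᵢ, natal year, clutch
date, sex], pedigree-structured breeding values (cov(*a*) = *V*_A **A**),
random natal-brood and cohort-year effects, and the latent residual
variance fixed to 1 by convention. Fitting is by Gibbs sampling with
Pólya-Gamma data augmentation; every derived statistic (cohort trends in
*a*, *g·q* and *u*, cohort variance and skew, back-transformed survival
probabilities) is computed on full posterior distributions, never on
per-individual point estimates. A gene-dropping null — neutral breeding
values simulated down the observed pedigree, one replicate per posterior
draw of *V*_A — calibrates whether the observed trend in mean breeding
value exceeds drift.

## Worked example

`examples/trends_and_drift.py` simulates a reduced study (10 cohorts of
~60 phenotyped chicks, one immigrant per year, true *g* = −2.36,
*V*_A = 0.36), fits the animal model and prints the posterior genetic
trends:

```
breeding value a       slope +0.043/yr [-0.022, +0.158] P(>0) = 0.86
immigrant effect g*q   slope -0.032/yr [-0.054, -0.009] P(>0) = 0.00
total value u          slope +0.011/yr [-0.062, +0.135] P(>0) = 0.43

P(observed a-trend exceeds drift) = 0.806
```

Mean breeding value rises under selection (+0.043 latent units per year,
probably faster than drift alone), but the immigrant genetic effect *g·q*
falls at nearly the same rate as immigrant ancestry accumulates, so the
total additive genetic value *u* barely moves — an approximate
migration–selection balance. The other example scripts cover pedigree
coefficients (`pedigree_coefficients.py`), the simulator
(`simulate_study.py`), the model summary table (`fit_animal_model.py`) and
cohort selection gradients (`selection_gradients.py`).

A thin CLI orchestrates the same pipeline from the shell:

```bash
genegroups all --seed 1 --out results/run1
```

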