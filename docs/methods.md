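# Methods

This note records the statistical models implemented in `genegroups`, the
numerical choices behind them, what the synthetic-data generator does and
does not emulate, and the known limitations.

## Pedigree quantities

**Genetic-group coefficients.** Founders (both parents unknown) are
assigned to the IMMIGRANT or NATIVE group from their flag; *q* of a founder
is 1 or 0 and every non-founder gets the parental average, processed in
topological order (Kahn's algorithm, ties broken by input order so matrix
indexing is reproducible). An unknown single parent contributes as a
phantom NATIVE founder (*q* = 0, *f* = 0, unrelated to everyone); this
keeps the native group as the zero-mean base population. The two groups
partition the genome, so the native coefficient is 1 − *q*.

**Inbreeding.** *f*ᵢ is the kinship of the parents, computed by the exact
recursive kinship algorithm with memoisation (no approximation; pedigrees
here are ~10³ individuals, so exactness is cheap). Tests cross-check it
against an independently coded tabular relationship matrix.

**Inverse relatedness.** A⁻¹ is assembled by Henderson's rules with
inbreeding-corrected Mendelian-sampling variances
*d*ᵢ = 0.5 − 0.25(*f*_sire + *f*_dam) when both parents are known,
0.75 − 0.25 *f*_known with one known parent, and 1 for founders. The
factorisation A⁻¹ = T′D⁻¹T (T = I minus the parent-average matrix) is kept
alongside and reused as the exact square root of the genetic prior inside
the sampler.

## The animal model and its sampler

The phenotype is binary local juvenile survival. On the latent scale,

  l = Xβ + Z_a a + Z_b b + Z_c c + e,  y ~ Bernoulli(logit⁻¹(l)),

with a ~ N(0, V_A A), brood effects b ~ N(0, V_brood I), cohort-year
effects c ~ N(0, V_year I) and e ~ N(0, 1) fixed, which identifies the
latent scale (the convention under which all variances and effect sizes
are expressed). Year appears twice — as a centred continuous fixed effect
(environmental trend) and as the random cohort factor — deliberately, with
partial confounding accepted because both are reporting targets. Sex is a
single male-vs-female contrast; clutch date is centred. Fixed effects have
N(0, 10¹⁰) priors; variance-component standard deviations have half-Cauchy
priors (default scale 1, configurable).

Breeding values are sampled for **all** pedigree members, ancestors
included, so trend and drift analyses can address any subset.

**Sampler.** Pólya-Gamma augmentation: given ω ~ PG(1, l), the likelihood
contribution is Gaussian in pseudo-data z = (y − ½)/ω with variance 1/ω;
integrating the unit latent residual gives observation variance 1/ω + 1.
Each sweep:

1. ω | l elementwise (vectorised exact Devroye sampler, implemented in
   `_polyagamma.py` and verified against closed-form moments and the
   sum-of-gammas representation);
2. all location effects (β, a, b, c) jointly from one sparse Gaussian
   draw: the random blocks are factorised sparsely, the p dense
   fixed-effect columns enter by a Schur complement, and the perturbation
   vector is assembled from the model's own square roots (Z′W^{1/2},
   T′D^{-1/2}/√V_A, ...), so the draw is exact without dense algebra;
3. each variance component in turn by a slice-sampling update of log V
   from its **marginal** likelihood — its own effects and the latent
   residual integrated out, conditioning only on (ω, z) — followed by an
   exact conditional redraw of those effects. For brood and year the
   marginal is closed-form per group; for V_A the log-determinant and
   quadratic form come from a sparse Cholesky of Z′WZ + A⁻¹/V_A.

The marginal variance updates are what make the chain usable: conditioning
variance draws on sampled effects (the textbook inverse-gamma update)
leaves lag-1 autocorrelations above 0.95 for binary traits, whereas this
scheme typically yields ~0.1–0.2 for fixed effects and ~0.6–0.8 for V_A.
The sampler reports lag-1 autocorrelations and warns above a threshold
(default 0.05); `fit_with_target_autocorr` doubles thinning until the
target is met. Sparse factorisations reuse a symbolic analysis computed
once per model (`_sparsechol.py`, numba kernels; the fill-reducing
ordering is taken from SuperLU's minimum-degree routine).

**Correctness checks.** The Gaussian-response variant with variances fixed
at truth reproduces BLUP/GLS from directly solved mixed-model equations
(posterior means within Monte-Carlo error, posterior standard deviations
within 1%); the binary path with variances pinned reproduces a posterior
computed by two-dimensional quadrature over a logistic-normal likelihood;
and at study scale the model recovers its own generative parameters with
near-nominal interval coverage (tests).

**No-groups variant.** `fit_no_groups_variant` drops the q regression,
modelling one unstructured base population. With a genuine negative g and
rising q it absorbs the group-mean trend into breeding values and inflates
apparent V_A — the package reproduces this inflation direction as a
validation experiment.

## Derived posterior quantities

All derived statistics are computed per posterior draw (never from
per-individual posterior point estimates, whose moments are biased):
u = a + g·q exactly; individual-level OLS slopes of a, g·q and u on natal
year over the focal phenotyped subset (individuals as units, so cohort
sizes act as implicit weights; slope additivity slope_u = slope_a +
slope_gq holds exactly); cohort population variance (divide by n) and
moment skew (third central moment / variance^1.5, no small-sample
correction, undefined below cohort size 3); variance/skew contrasts of u
versus a across pairwise draws. Back-transformation to the probability
scale evaluates the inverse logit of the fixed-effect predictor at a
covariate setting with the focal genetic component at its cohort mean,
random effects at zero — conditional, not population-averaged,
probabilities.

## Gene-dropping drift null

Neutral breeding values are simulated down the observed pedigree: founder
values (native and immigrant alike) ~ N(0, V_A), non-founders get the
parental average plus a Mendelian deviation with variance
V_A(0.5 − 0.25(f_sire + f_dam)) — the inbreeding-corrected rule that
matches the A matrix used in fitting (an uncorrected 0.5·V_A option is
provided). One replicate is generated per retained posterior draw using
that draw's V_A, the trend slope is computed on the same focal subset, and
the proportion of positive paired differences estimates the posterior
probability that the observed trend exceeds drift. Under a null generator
(no selection, g = 0) this probability is approximately uniform across
datasets, mean one half — verified by a calibration experiment.

## Selection gradients

Within each cohort the gradient is the OLS slope of relative fitness
(individual local lifetime offspring divided by the cohort mean) on
survival standardized to unit variance (population SD, consistent with the
population-variance convention elsewhere). Cohorts with no survival
variance or zero mean fitness are skipped with a warning; the grand mean
is unweighted across cohorts. The gradient is invariant to rescaling
reproductive success and is structurally positive whenever any survivor
reproduces.

## The synthetic-data generator

`simulate_population` is a forward individual-based simulation of the
study design: a small closed native founder pool; Poisson(1) immigrants
per year arriving as adults with q = 1 and breeding immediately (their own
survival is not modelled); seasonal monogamous pairing with 28% extra-pair
paternity; 1–3 sequential broods of 1–4 chicks (mean brood size 2.2);
chick survival drawn from the inverse logit of the full latent predictor
(including brood and year effects and the unit residual, matching the
fitted model exactly); recruitment of survivors truncated at a fixed adult
capacity by random culling; adult annual survival 0.55. Kinship is tracked
incrementally with the same recursion the pedigree module uses, so the
truth record's q and f round-trip exactly.

Default parameters are the study conditions the package is designed
around: 26 cohorts, latent variances (0.36, 0.19, 1.11), g = −2.36,
inbreeding-depression slope −8.92, clutch-date slope −0.01/day, year trend
−0.06/yr, sex contrast 0.56. Demographic defaults (12 native founders,
18 burn-in years, adult capacity 55, intercept −0.4) were chosen once so
that the realized design matches the target dimensions: ~95 chicks per
cohort, mean q rising from ~0.30 to ~0.56, mean f ~0.12. Realized survival
(~0.32 female / 0.40 male) sits somewhat above the ~0.23/0.31 target
because the simulated population self-equilibrates: the selection response
in breeding values balances the environmental year trend and the
immigrant drag, and absorbs intercept changes. We accepted this rather
than distort the stated latent-scale parameters.

**What the generator does not emulate:** spatial/territory structure,
non-additive effects (heterosis), emigration distinct from mortality, a
population bottleneck, and age structure beyond an adult survival rate.
Passing tests therefore demonstrate correctness of the estimation
machinery under the stated generative model, not robustness to these
real-data complications.

**Selection and censored cohorts.** With selection on and burn-in cohorts
unphenotyped, selection acts on records the model never sees; it is then
non-ignorable and the posterior for g is biased toward stronger negative
values (we measured ≈ −1.5 latent units at reduced scale). This mirrors a
genuine limitation of pedigree analyses whose early cohorts lack
phenotypes. The calibration experiments therefore use `reduced_config`
(10 cohorts of ~60, burn-in 0, every selected-on cohort phenotyped), under
which posterior-mean bias for g is within a few percent and interval
coverage is near nominal. Replicate experiments re-draw with an offset
seed when a simulated population crashes or dwindles below 45 phenotyped
chicks per cohort; binary animal models on degenerate data have a genuine
quasi-separable posterior tail (V_A → ∞ fits perfectly) that no sampler
fixes.

## Experiment sizes

Chosen as the package's working defaults: recovery, 50 replicate reduced
studies with 700-sweep chains; drift calibration, 20 null replicates;
drift power, 20 replicates at 18 cohorts with V_A = 1.5 and V_year = 0.5
(strong selection on a strongly heritable trait); variance-inflation
comparison, 20 paired fits with 1500-sweep chains (posterior-mean V_A is
heavy-tailed and needs the longer chains); headline run, the 26-cohort
default design with 4000 sweeps thinned by 2.
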