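# Methods

This note records the model, the synthetic data-generating process, the
numerical choices and the known limitations of the `healthmrp` pipeline.

## Model

Each outcome (literacy, numeracy, ICT) is modelled independently on its own
subsample of the source survey as a Bernoulli-logit regression

    y_i ~ Bernoulli(pi_i)
    logit(pi_i) = b0 + sum_x b^x_{level_x(i)} + u_{q(i)}

* Fixed effects use reference-level-zero coding: for every covariate one
  level is the reference and its coefficient is pinned at 0, so reported
  effects are contrasts against it.  The default references are: age 16–44,
  female, non-white, English not first language, not UK born, not owning
  home, not working, qualification ≤ level 1, income < 10k, higher
  (managerial/professional) job status.
* The deprivation quintiles (IMD 1–5, 1 = most deprived) are partially
  pooled: `u_q ~ N(mu_IMD, sigma_IMD^2)` with all five quintiles receiving
  an effect.  Because both `b0` and `mu_IMD` are kept (with priors), only
  their sum is identified; every reported quantity (cell probability,
  prevalence, contrast) depends on identified combinations only.
* Priors: `N(0, 2.5)` for the intercept, fixed effects and `mu_IMD`;
  `HalfNormal(1)` for `sigma_IMD`.  These regularise without dominating at
  sample sizes in the thousands.  `PriorSpec.vague()` inflates all scales
  100-fold for a near-flat sensitivity run.

### Sampling

The posterior (20 parameters for the default schema) is sampled with an
affine-invariant ensemble MCMC (emcee), using an 80/20 mixture of
differential-evolution and snooker moves, which mixes well at this
dimensionality.  Implementation choices:

* The likelihood is collapsed to unique covariate patterns (binomial form),
  making one density evaluation O(patterns × parameters).
* The random-effect block is sampled non-centred (`u = mu + sigma·z`) with
  `log sigma` as the free parameter (half-normal prior plus Jacobian).
* Walkers start near the penalised posterior mode (L-BFGS with analytic
  gradients) with small Gaussian jitter.
* `chains` independent ensembles are run (64 walkers each; at least 256
  post-warmup steps), and each ensemble's flattened history is thinned
  step-major to exactly `draws` retained draws, so the draw count is always
  `chains × draws`.  Retained draws are nearly uncorrelated at these
  settings.
* Split-R-hat and bulk ESS are computed per parameter (arviz) across the
  retained chains; a warning is emitted when any R-hat exceeds the
  threshold (default 1.01).  At the desk-scale profile R-hat occasionally
  sits near 1.01–1.04 on `sigma_IMD`; the reporting quantities (prevalences,
  contrasts) have ESS in the hundreds.
* Defaults: 4 chains × 1000 warmup steps × 1000 retained draws; the
  desk-scale test profile is 2 × 500 × 500.  Both are pure functions of the
  seed: identical settings and seed reproduce draws bitwise.

## Post-stratification frame

The frame enumerates all covariate-level combinations in declared schema
order (11,520 cells for the default 11-covariate schema) and assigns weights
from three blocks:

1. the joint of (age, sex, ethnicity, working, home ownership) estimated as
   relative frequencies from target-area microdata;
2. the joint of (English, UK born, qualification, income, job) estimated
   from labour-force microdata and raked to target-area margins by IPF;
3. the IMD-quintile margin pooled from an LSOA decile population table
   (quintile q pools deciles 2q−1 and 2q).

**Block independence is the frame-construction assumption**: the three
blocks are combined as a product, so cross-block associations (e.g. between
ethnicity and English) are not represented.  This is forced by the data
situation — no source observes covariates across blocks jointly — and is the
main structural approximation of the frame.

IPF cycles the target margins in declared order, measures convergence after
each full cycle as the maximum absolute margin deviation (default tolerance
1e-10, maximum 1000 cycles; tables of this size converge in tens of cycles),
preserves structural zeros exactly, and raises on infeasible targets rather
than inventing population mass.  IPF leaves every conditional odds ratio of
the seed unchanged; this invariance is the main correctness oracle in the
tests.

## Counterfactual contrasts (MRP-ATE)

For a focal (variable, level), both arms are counterfactual: all weight in
each stratum of the remaining covariates is moved onto the focal level, and
onto the reference level, and the post-stratified prevalences are
differenced per draw.  The computation uses the algebraically identical
stratum-difference form, which yields exact zeros for null coefficients and
exact antisymmetry under arm swapping.  Summaries are the posterior mean and
equal-tailed 95% intervals (linear-interpolation quantiles); reporting
rounds to 3 decimals while unrounded values are retained.

These are predictive comparisons: they summarise the fitted model's
structure over the target population and assume a covariate can be changed
without moving the others.  No causal identification is claimed.

A property worth knowing when validating against ground truth: the posterior
*mean* of a sigmoid functional is not an exactly unbiased estimate of the
functional at the true parameters — averaging the inverse-logit over
posterior uncertainty flattens contrasts by a term of order the posterior
variance of the linear predictor.  At n = 4000 this smoothing deviation is
up to ~0.02 on the probability scale for contrasts whose reference level is
rare in the source, and the partially pooled IMD contrasts are additionally
shrunk toward the pooled mean by design.  The acceptance tests therefore
check consistency (systematic deviation within 3 Monte-Carlo standard
errors across replicates), not exact unbiasedness.

## Ranking

Contrasts are ranked per draw by |ATE| (rank 1 = largest; absolute values
because effect direction is a coding choice), ties broken by declaration
order (measure-zero for continuous draws).  SUCRA and expected rank satisfy
`E[rank] = n − (n−1)·SUCRA` exactly on the unrounded values; the published
rounded columns need not be mutually consistent, so both rounded and
unrounded columns are exported.  The reporting rankogram keeps the first
four ranks and items with cumulative probability ≥ 0.25; the unfiltered
table is always written alongside.

## Synthetic data

The generator emulates the study's input landscape from a known truth:

* **Source survey** (default n = 4000): covariates drawn independently with
  national-like level frequencies (mostly UK-born, white,
  English-first-language); an optional log-odds tilt induces pairwise
  associations.  Outcomes are Bernoulli draws from the true multilevel
  logistic process; subsamples are nested heads of one seeded permutation
  with fractions 0.80/0.61/0.31 (matching the planned assessment subsets of
  the source skills survey, 5818/4396/2274 of 7230).
* **Target microdata** (n = 3000 over the resident-survey block) drawn from
  a tilted joint with borough-like margins: young, diverse, mostly renting.
* **Labour-force microdata** (n = 3000 over the remaining block) drawn from
  a *national-like* joint tilted the other way, so its margins genuinely
  differ from the emitted local raking targets and raking is non-trivial.
* **LSOA table**: 164 areas, deciles concentrated in 2–4, Poisson
  populations around 2100.
* **True parameters** per outcome echo the field's recurring findings
  (qualification strongly protective everywhere; English as first language
  protective for literacy; age 45+ sharply worse for ICT; lower job status
  worse everywhere).  Working status carries an exactly-zero effect in all
  outcomes, providing a known null for calibration checks.  IMD quintile
  effects are fixed small values (spread ~0.15–0.25 logits).

Because the generator's blocks are mutually independent (matching the
frame-construction assumption) and all parameters are known, the implied
population prevalence and every contrast are exactly enumerable, which is
what the recovery tests compare against.

What the generator does **not** emulate: survey nonresponse and design
weighting, interviewer and mode effects, cross-block covariate dependence,
within-borough geography below the IMD margin, and measurement error in the
skill grades.  Passing tests therefore demonstrate correctness of the
machinery and calibration under the stated process, not robustness to those
real-data features.

## Problem sizes and profiles

Tests and the acceptance script run the desk-scale profile (2 chains × 500
warmup × 500 draws; n = 4000/3000/3000). The replicate battery behind the
statistical acceptance checks uses 20 independent surveys at those sizes
with all seeds derived from one fixed seed sequence.  The full profile
(4 × 1000 × 1000) is the default for analyses.

## Degenerate inputs and failure modes

Empty schemas, unknown levels (reported with record and variable),
single-class outcomes (separation), misaligned cell indexes, infeasible
raking targets, zero total population and non-converged IPF all raise typed
errors naming the offending stage or input; the pipeline wrapper prefixes
stage names.  Cell probabilities are computed without clipping; with the
default priors logits stay far from overflow.

## Known limitations

* Block independence in the frame (above) and the simplistic binary
  ethnicity coding inherited from the source survey's schema.
* One model per outcome; no interactions, no non-IMD random effects, no
  survey-weighted likelihood.
* ATT, stochastic interventions and heterogeneous-effect variants are out
  of scope; so is any weighting of rankings by population size or budget.
* The printed cell count depends on the schema; the default factorisation
  (2^8 × 3 × 3 × 5 = 11,520) follows the declared category counts, and the
  schema document is the single place to change it.
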