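# healthmrp

Estimating local-population determinants of low health literacy — and ranking
them for policy prioritisation — when no single dataset contains both local
demographics and health-literacy outcomes.

The package is aimed at public-health analysts doing small-area estimation:
it combines a national skills survey (which has literacy, numeracy and ICT
outcomes but is not local) with local covariate data (which has no outcomes)
through **multilevel regression with post-stratification (MRP)**, derives
counterfactual effect contrasts over the local population, and converts them
into probabilistic priority rankings.

## The method

**Multilevel regression.** For a binary response `y_i` (1 = not health
literate, defined by thresholding five-level skill grades: L2 for literacy,
L1 for numeracy, EL3 for ICT), fit

```
pi_i = logit^-1( b0 + sum_x b^x_{gamma_x[i]} + u_{q[i]} ),
u_q ~ N(mu_IMD, sigma_IMD^2),
```

with reference-coded fixed effects for ten categorical covariates (age, sex,
ethnicity, English as first language, UK born, home ownership, working
status, qualification, income, job status) and partially pooled random
effects for the five area-deprivation (IMD) quintiles.  Priors are weakly
informative: N(0, 2.5) on intercept and coefficients, HalfNormal(1) on
`sigma_IMD`.  The posterior is sampled with an ensemble MCMC
(differential-evolution moves) over the 20-parameter model.

**Post-stratification.** The target population is described by a frame of
`|S| = 11,520` covariate cells with weights `w_c = N_c / N`, assembled from
three blocks combined under independence: a joint estimated directly from
local resident-survey microdata, a second joint from national labour-force
microdata raked to local margins by iterative proportional fitting (IPF),
and an IMD-quintile margin pooled from an LSOA population table.  The
post-stratified prevalence is `pi_mrp = sum_c w_c * pi_c`.

**MRP-ATE.** For each covariate level, the effect contrast is fully
counterfactual: `pi_mrp(everyone at level) − pi_mrp(everyone at reference)`,
computed per posterior draw.  Negative values are improvements.  These are
predictive comparisons over the target population, not identified causal
effects.

**Priority ranking.** Within each draw, contrasts are ranked by absolute
effect size; aggregating over draws gives cumulative rank probabilities
`P_ir`, the SUCRA summary `sum_{r<=n-1} P_ir / (n-1)`, and expected ranks
`n − (n−1)·SUCRA`.

Because the real local microdata are license-restricted, a first-class
synthetic-data module generates every input from a known multilevel logistic
ground truth, which also enables parameter-recovery and calibration testing.

## Worked example

The numbered scripts under `analysis/` run the whole study at desk scale
(`python analysis/01_generate_inputs.py` through `05_rank_determinants.py`),
writing tables under `results/`.  With the default seed (42) the pipeline
prints, among other things:

```
frame: 11520 cells, weights sum 1.000000000000, raking margin deviation 5.72e-11
largest source-vs-target gaps (literacy subsample):
  ethnicity=white      source 0.90 target 0.28  diff +0.62
strongest contrasts per outcome (mean change in P(not literate)):
  literacy  qualification=>=level2   -0.276 [-0.310, -0.245]
  literacy  english=yes        -0.236 [-0.283, -0.185]
  ict       age=45+        +0.276 [+0.227, +0.324]
top determinants by SUCRA (absolute MRP-ATE ranking):
  literacy  qualification=>=level2   SUCRA  99%  E[rank] 1.1
  ict       age=45+        SUCRA 100%  E[rank] 1.0
```

Reading: the synthetic source and target populations diverge sharply (62
percentage points on ethnicity), which is exactly the situation MRP is built
for; moving everyone to a level-2-or-higher qualification lowers the
population probability of not being literacy-health-literate by 0.276 (95%
credible interval [−0.310, −0.245]); age 45+ is almost surely the top-ranked
determinant for ICT.  Bulky intermediates (the frame, posterior draws,
per-draw contrasts) are regenerated by the scripts and not kept in the
repository.

The same pipeline is scriptable (`healthmrp run --seed 7 --outdir out
--mcmc-profile test`) or callable from Python via
`healthmrp.run_pipeline(PipelineConfig(...))`.

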