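# Methods

## The estimation problem

National child-health surveys are stratified by state and provide reliable
direct prevalence estimates only for large geographies. `mlsae` implements
the multilevel small-area estimation (SAE) workflow that bridges this gap for
a binary outcome (childhood obesity): fit a multilevel logistic model to the
unit-record survey, transfer the fitted risk surface onto census block
groups, and post-stratify with census demographic counts to obtain a
prevalence estimate for every block group, county, state and the nation.

## Model

For child *i* in zip *z(i)*, county *c(i)*, state *s(i)*:

    logit Pr(y_i = 1) = x_i' beta + u_{s(i)} + v_{c(i)}
    u_s ~ N(0, sigma2_state),   v_c ~ N(0, sigma2_county)

All covariates are categorical with declared reference levels: individual
sex, age group (10–14 vs 15–17) and race/ethnicity (8 levels); zip-level
median-household-income octile (8), lifestyle class (12) and urbanization
class (11); county-level income octile (8) and the 6-level NCHS urban–rural
class. The full fixed-effect design has 50 columns including the intercept.
Four random-intercept structures are supported: state, county, zip, and
county nested in state; nesting is purely structural because county ids are
globally unique.

### Laplace maximum likelihood

The marginal likelihood integrates over the random intercepts; we replace
the integral by its Laplace approximation around the conditional mode
`b_hat`:

    ll(beta, sigma2) = l_cond(beta, b_hat) - b_hat' D^-1 b_hat / 2
                       - log det(I + D^{1/2} Z'WZ D^{1/2}) / 2

with `W = diag(p(1-p))` evaluated at the mode. Fitting follows the
penalized-IRLS formulation used by lme4's `glmer`: for each trial value of
`log sigma2`, `(beta, b)` are maximized jointly by damped Newton iteration on
the penalized log-likelihood, the Laplace objective is evaluated there, and a
derivative-free outer optimizer (bounded Brent for one variance, Nelder–Mead
for two) profiles over `log sigma2`. For small problems (n ≤ 2000, ≤ 12
fixed effects) a Nelder–Mead polish then re-optimizes the full Laplace
objective over `(beta, log sigma2)` with the modes profiled out; this removes
the small discrepancy caused by the log-determinant's dependence on `beta`
and brings tiny-sample fits into agreement with adaptive Gauss–Hermite
quadrature (the test suite's independent oracle) to ≤ 0.05 in log-likelihood.
At survey scale the polish is numerically irrelevant (the log-determinant
term is O(q) against an O(n) likelihood) and is skipped.

Numerical choices:

- Variance components are optimized as `log sigma2` on [-15, 4]; a fit at the
  lower bound is reported as `sigma2 = 0` with a boundary flag (variance
  components of overparameterized area levels routinely collapse to zero).
- Inner Newton convergence: gradient infinity-norm below `1e-10 · max(n, 100)`,
  with step halving on the penalized objective; outer tolerance `xatol 1e-6`
  on `log sigma2`; cap 200 outer iterations.
- Fixed-effect standard errors come from the beta block of the inverse joint
  `(beta, b)` Hessian at the optimum (Schur complement), the same observed-
  information quantity glmer reports. Variance-component SEs use the delta
  method from a finite-difference Hessian of the profile objective in
  `log sigma2`; they are reported as missing at a boundary.
- A singular information matrix (e.g. a covariate level with no
  observations) yields missing SEs but a returned fit; coefficients beyond
  ±25 on the logit scale raise a separation diagnostic instead of returning
  a silently divergent fit.
- `aic = -2·ll + 2·(n_fixed + n_variance_components)`.

### Adequacy and selection

Model adequacy compares each full model with its null (random effects only)
counterpart: `100·(sigma2_null − sigma2_full)/sigma2_null` per random term,
adequate when every term reaches at least 40%. Among the full candidates the
smallest AIC wins; ties break toward fewer parameters, then declaration
order.

## Prediction and Monte-Carlo intervals

The predictive model is the *refitted* reduced term set — sex, age, race,
income octile, lifestyle, plus state random intercepts — not a subset of the
full fit's coefficients, because the workflow drops the county
terms and urbanization as non-significant and refits before predicting.
Zip-level coefficients are applied to block-group covariates (the
coefficient-transfer assumption). Each census cell (block group × sex × age
× race) gets risk `expit(x'beta + u_s)` with the state effect at its fitted
conditional mode; the block-group prevalence is the census-count-weighted
mean of its cell risks, and coarser geographies are count-weighted means of
block groups.

Intervals: 1,000 Monte-Carlo draws redraw every fixed-effect coefficient
independently from `Normal(estimate, SE)`; the post-stratified prevalence is
recomputed per draw and the 2.5th/97.5th percentiles bound the 95% interval
(percentile intervals respect [0, 1]); CV = draw SD / point estimate.
Aggregated intervals are computed from draw-wise aggregated prevalences,
never by averaging bounds. Two deliberate simplifications, both standard in this workflow: coefficients are drawn without their
covariance (independence typically *overstates* linear-predictor variance
because coefficient estimates are negatively correlated through shared
reference cells), and state effects are held fixed across draws (understating
uncertainty). In the package's coverage experiment these act in opposite
directions and the realized block-group coverage of a nominal 95% interval
is ≈ 97–99%.

## Validation protocol

Direct estimates are Hájek ratios `sum(w·y)/sum(w)` with linearized variance
`sum(w²(y−p)²)/(sum w)²` treating weights as fixed — no finite-population
correction or design-stratum variance, since the synthetic weights are
simple inverse sampling fractions. The reliability screen keeps geographies
with n ≥ 30 sampled children and relative SE below 0.3. Model and direct
estimates are compared by paired t-test, median-unbiased difference
quartiles, a count of non-overlapping 95% intervals, and a Pearson
correlation curve over minimum county sample sizes {15, 30, 50, 100, 150,
200}.

A property of the screen worth knowing: at prevalence ≈ 0.16, the relative-SE
rule can only pass a county with 30 ≤ n ≲ 100 if its *observed* estimate is
high (`p_hat > 1/(1 + 0.09 n)`), so over such counties the kept direct
estimates are conditionally biased upward and are not a neutral benchmark.
The calibration experiments therefore use two designs: the paired-t and
median-difference checks run on a scenario with large county samples (2
counties per state, 800 children per state, uniform within-state county
sampling) where the screen keeps every county and selects on nothing, and
the correlation-curve check runs on a county-size gradient
(Dirichlet(0.5) county sampling shares, 6 counties per state) which is
exactly the regime the curve is meant to probe.

## Synthetic data generator

The generator emulates the structure of the real inputs without any
download: ~51 states with a few hundred sampled children each (the real
survey has a mean of 865 per state; scaled-down runs use 400–800), balanced
county/zip/block-group nesting, uniform categorical area covariates, Poisson
census counts per block group × sex × age × race cell, and outcomes drawn
from an explicit true multilevel logit model whose default coefficient
surface is the reference national childhood-obesity model (intercept
−3.4529, state variance 0.0530, overall prevalence ≈ 16%).

Deliberate defaults, each configurable:

- Demographic marginals are uniform over categories (the survey's joint
  margins are not published); weights are inverse sampling fractions.
- Within-state sampling is simple random sampling of children; county
  shares can be made unequal via a Dirichlet concentration parameter.
- Block-group covariates are drawn independently of zips by default; the
  `bg_covariate_source="zip"` knob copies them from the county's zips so the
  coefficient-transfer assumption holds exactly — used in calibration
  studies of the prediction pipeline.

What the generator does *not* emulate — and hence what passing tests do not
show about real data: spatial adjacency and geographic clustering of
covariates (areas are exchangeable here, so covariates explain essentially
none of the *state*-level variance, unlike the real analysis where they
explain ~60%), complex survey weighting and nonresponse, measurement error
in parent-reported height/weight, and real census cell-count error.

## Problem sizes in the shipped experiments

Recovery runs use 51 states × 400 children (20 replicates), coverage uses
1,632 block groups with 1,000 draws, and the validation calibrations use 20
replicates of the two designs above; these sizes give Monte-Carlo SEs small
enough for the asserted tolerances while keeping the whole suite inside a
couple of minutes of compute.

## Known limitations

- One-dimensional Laplace accuracy degrades for very sparse clusters (a few
  Bernoulli observations per area with large variance); the engine is
  intended for survey-scale areas.
- No survey-weighted pseudo-likelihood: models are fitted unweighted, as is standard
  in this workflow; weights enter only direct estimation.
- No crossed random effects, random slopes, or PQL.
- States absent from the survey would predict with effect 0 (population
  average); synthetic runs always cover all states.
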