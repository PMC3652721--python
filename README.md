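# mlsae — multilevel model-based small-area estimation of prevalence

`mlsae` estimates the prevalence of a binary child-health outcome (childhood
obesity) for geographies far too small for direct survey estimation — census
block groups — by combining a state-stratified health survey with census
demographic counts in a multilevel modelling framework. It is aimed at
epidemiologists and survey statisticians who want a fully testable,
end-to-end implementation of the workflow: model fitting, post-stratified
prediction, Monte-Carlo intervals, and validation against direct estimates,
exercised on synthetic data with known truth.

## The model

For child *i* in zip *z(i)*, county *c(i)*, state *s(i)*:

    logit Pr(y_i = 1) = x_i' beta + u_{s(i)} + v_{c(i)},
    u_s ~ N(0, sigma2_state),  v_c ~ N(0, sigma2_county)

with categorical covariates for sex, age group, race/ethnicity (individual
level), income octile, lifestyle and urbanization class (zip level), and
income octile and urban–rural class (county level). Models are fitted by
maximum likelihood under the Laplace approximation (the glmer-style
penalized-IRLS formulation); adequacy is judged by the share of null-model
between-area variance explained by the fixed effects (≥ 40% per random
term), and the final structure is chosen by smallest AIC.

Prediction refits the reduced term set (sex, age, race, income octile,
lifestyle + state random intercepts), applies the zip-level coefficients to
block-group covariates, and post-stratifies: each block-group prevalence is
the census-count-weighted mean of its sex × age × race cell risks
`expit(x'beta + u_s)`. 1,000 Monte-Carlo draws of the coefficients from
`Normal(estimate, SE)` give percentile 95% intervals and CVs; counties,
states and the nation aggregate the per-draw prevalences with census
weights. Validation compares model-based with direct (weighted) county
estimates after a reliability screen (n ≥ 30, relative SE < 0.3), via paired
t-tests, difference quartiles and a correlation-versus-minimum-sample-size
curve. See `docs/methods.md` for the full account.

## Worked example

```python
from mlsae import (generate_geography, TrueModel, simulate_survey,
                   generate_population_cells, ModelSpec, BinomialGLMM,
                   PredictiveModel, mc_prevalence_draws, variance_explained)
from mlsae import categories as cat

geo = generate_geography(20, 3, 4, 5, seed=1)            # 20 states, 60 counties
true = TrueModel.draw(geo, seed=2, sigma2_state=0.053)   # known truth
survey = simulate_survey(geo, true, n_per_state=500, seed=3)
cells = generate_population_cells(geo, mean_children_per_bg=60.0, seed=4)

null = BinomialGLMM.from_records(survey, geo,
    ModelSpec(fixed_terms=[], random_terms=["zip"])).fit()
full = BinomialGLMM.from_records(survey, geo, ModelSpec(random_terms=["zip"])).fit()
print(f"zip-level variance: null {null.sigma2['zip']:.4f} -> full "
      f"{full.sigma2['zip']:.4f} ({variance_explained(null, full, 'zip'):.1f}% explained)")

reduced = BinomialGLMM.from_records(survey, geo,
    ModelSpec(fixed_terms=list(cat.PREDICTIVE_TERMS), random_terms=["state"])).fit()
draws = mc_prevalence_draws(PredictiveModel.from_results(reduced, geo),
                            cells, geo, n_draws=1000, seed=5)
print(draws.to_frame().head(3).to_string(index=False))
nat = draws.aggregate("national").to_frame()
print(f"national prevalence {100*nat['estimate'].iloc[0]:.1f}% "
      f"(95% CI {100*nat['ci_low'].iloc[0]:.1f}-{100*nat['ci_high'].iloc[0]:.1f})")
```

prints

```
zip-level variance: null 0.0861 -> full 0.0000 (100.0% explained)
 geo_id level  n_children  estimate   ci_low  ci_high  ci_width       cv  n_draws  seed
B000000    bg        74.0  0.189695 0.121036 0.283086  0.162050 0.219985     1000     5
B000001    bg        77.0  0.083831 0.050962 0.134623  0.083661 0.263847     1000     5
B000002    bg        76.0  0.191382 0.124540 0.284440  0.159900 0.220573     1000     5
national prevalence 15.3% (95% CI 11.2-20.9)
```

The zip-level null variance collapses to zero in the full model because the
synthetic zip covariates carry all between-zip signal; each block-group row
shows the post-stratified estimate, its Monte-Carlo 95% interval, the
interval width and the CV, and the national line is the census-weighted
aggregate of all block-group draws.

The same pipeline runs from the shell, driven by a YAML config:

```bash
mlsae run-all --config examples/config.yaml --seed 1
```

writing survey/census CSVs, an adequacy table (null vs full variances and %
explained per structure), a coefficient table for the AIC-selected model,
SAE CSVs per geography level with a CI/CV summary table, and the
model-vs-direct comparison report.

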