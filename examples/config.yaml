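# Example run configuration for the mlsae pipeline.
# Any omitted key falls back to the package default; unknown keys are rejected.

seed: 1
out_dir: outputs

geography:
  n_states: 20
  counties_per_state: 3
  zips_per_county: 4
  bgs_per_county: 5
  # "independent" (default) or "zip" (block groups copy covariates from
  # their county's zips, making coefficient transfer exact)
  bg_covariate_source: independent

true_model:
  intercept: -3.4529          # logit-scale baseline risk (~3.1% for the reference child)
  sigma2_state: 0.0530        # between-state variance of the true model
  sigma2_county: 0.0
  coefficients: default       # the published national coefficient surface
  reduced: false              # true = drop county/urbanization terms from the truth

survey:
  n_per_state: 500
  county_concentration: null  # null = uniform; e.g. 0.5 = skewed county sizes
  state_child_population: 100000.0

population:
  mean_children_per_bg: 60.0

# random-intercept structures to fit (null + full each); AIC picks the winner
models: [state, county, state+county, zip]

n_draws: 1000                 # Monte-Carlo draws for 95% intervals

reliability:
  min_n: 30
  max_rse: 0.3

correlation_thresholds: [15, 30, 50, 100, 150, 200]
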