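# Methods

## Problem and estimand

Around a known exposure date (here: the onset of COVID-19 lockdowns in
March 2020, translated into a birth window starting December 2020), the
number of live births may change differently across socioeconomic groups,
shifting the *composition* of the birth cohort.  The estimand is, per group
g, the percentage-point difference

    delta_g = 100 * (p_g - q_g)

between the group's observed share `p_g` of births in the exposed window and
its counterfactual share `q_g` had pre-pandemic trends continued.  A
positive `delta_g` means group g makes up more of the pandemic-conception
cohort than expected.  Relative differences
`100 * (N_g_obs - N_g_cf) / N_g_cf` are reported alongside.

## Regression model

Counts are aggregated to calendar periods — ISO-8601 weeks (Monday start)
or calendar months — and each group is fitted separately by a Poisson
regression with log link and no offset (no population-at-risk denominator
is used; the model describes counts, not rates):

* intercept;
* linear and quadratic terms in the scaled period index
  `t' = (t - mean(t)) / n` (centring/scaling keeps the quadratic term
  well conditioned over multi-year series and is applied identically in the
  synthetic generator, so generative truth and fitted coefficients are
  directly comparable);
* week/month-of-year fixed effects, first week/January as reference.
  When a span contains ISO week 53 its indicator is merged with week 52
  (the level occurs in at most 1–2 years of data and cannot be estimated
  separately);
* optional level-shift indicators over stated shock windows (e.g. a
  Zika-epidemic dip, August–December 2016; whole-year data-collection
  breaks).  Shock windows may not overlap the exposure window;
* one indicator for the exposed window, whose coefficient is the average
  log level change over the entire window — no slope change or
  interaction.

The default exposed window is 2020-12..2021-12 (13 months) or
2020-W51..2021-W51 (54 weeks).  Fitting is iteratively reweighted least
squares (statsmodels GLM) with relative tolerance 1e-10 and at most 100
iterations; the coefficient covariance is the inverse Fisher information at
the optimum.  Non-convergence is flagged and any downstream use of a
non-converged fit raises.  Overdispersion and autocorrelated errors are
deliberately not modelled; the package keeps the simple homogeneous Poisson
form of the original design.

## Counterfactual totals and paths

The counterfactual total is the sum over exposed periods of
`exp(x_t' beta)` with the exposure column of `x_t` zeroed and the seasonal
and shock columns *retained*: totals must live on the observed count scale,
and the exposed window does not align exactly with whole seasonal cycles.
Its standard error uses the delta method, `g = sum_t mu_t x_t`,
`se = sqrt(g' Cov g)`; tests validate this against a 100,000-draw
parametric simulation from the coefficient covariance (agreement well
within 5%).

Plotted trajectories follow the opposite convention: *deseasonalised* paths
zero the seasonal and shock contributions (keeping the exposure effect) and
*counterfactual* paths additionally zero the exposure effect.  This split —
seasonal terms kept in totals, stripped in plots — is recorded in the run
manifest.

## Composition inference

Point compositions divide each group's total by the all-group sum, so
`sum_g p_g = sum_g q_g = 1` and `sum_g delta_g = 0` exactly.  The 95% CI
uses the three-step Monte-Carlo scheme (normal draw per group around the
counterfactual total, independent across groups; renormalise; difference
against the observed composition), with 10,000 replicates by default and
percentile bounds computed with linear interpolation between order
statistics.  One random stream per analysis fills group draws in fixed
group order per replicate, making results reproducible bit-for-bit given
seed and group order and independent of any parallelism.

Negative normal draws are left untruncated by default — in practice SEs are
far smaller than totals, so negative draws essentially never occur at
register scale — but each replicate must have a positive draw sum.  A
`truncate_at_zero` option clamps draws at 0 for tiny-count scenarios.
Relative-difference CIs reuse the same draws.

The percentile interval of this nonlinear functional need not contain the
plug-in point estimate; the code asserts only `lo <= hi`.

## Synthetic registers

The generator draws `y_gt ~ Poisson(mu_gt)` with the log-mean composed of
exactly the regression's terms, so estimation is correctly specified by
construction and closed-form truths exist for every downstream quantity
(`true_counterfactual_summary`).  Individual-level records can also be
generated (dates uniform within their period) and re-aggregated; a
missing-information category is simulated as just another group.  Default
experiment scales mirror a mid-sized country register: multi-year weekly
series at ~500 births per group-week, or monthly series at ~500–900 births
per group-month.

What the generator does *not* emulate: delayed registration, stillbirths
and in-utero selection, migration, within-week birth-day patterns,
overdispersion, and serial correlation.  Passing tests therefore show the
pipeline is correct and calibrated *for the model it assumes*, not that the
Poisson form is adequate for any particular real register.

## Calibration properties (computed by the test suite and acceptance script)

* The fitter matches a brute-force zooming-grid maximiser of the Poisson
  likelihood to 1e-4 on small series; the score identity
  `sum_t (y_t - mu_t) x_t = 0` and the fitted-total = observed-total
  identity hold to 1e-6.
* Over 200 replicate weekly registers with a true +7% exposure effect, the
  mean estimated relative difference is within 0.5 pp of 7% and 95% Wald
  CIs for the exposure coefficient cover the truth at the nominal rate.
* Under a null scenario the three-step MC interval covers the true delta
  (= 0) for each group at roughly 90%.  The ~5 pp undercoverage is a
  property of the procedure, not a bug: the interval propagates only the
  counterfactual-estimation uncertainty, while the observed composition is
  treated as fixed data, so the observed window's Poisson noise is not
  reflected in the interval.  At register scale that missing component is
  roughly 40% of the counterfactual variance.  Users comparing small groups
  should read the intervals as conditional on the observed cohort.

## Numerical and design choices

* Quintile assignment uses the 20/40/60/80 percentiles of a *pre-exposure*
  reference distribution only (linear-interpolation percentiles); values
  equal to a cutpoint fall in the lower quintile; Q5 is the highest score;
  missing scores get a "missing" label and form their own group.
* The maternal-age restriction "over 25" is implemented as strictly
  greater than 25.
* Seasonal levels absent from a data span are dropped from the design with
  a warning rather than producing an all-zero (rank-deficient) column.
* All randomness flows through numpy Generators seeded explicitly; the
  pipeline manifest records the config hash and every convention above, so
  a config + manifest reproduce all tabular outputs byte-for-byte.

## Limitations

* Single level-shift exposure effect: gradual rebounds within the window
  are averaged, not traced.
* Group-level independence is assumed in the MC scheme; competition
  between groups (births shifting between groups) would induce negative
  dependence and narrower true intervals.
* Equivalisation of household income, construction of deprivation indices
  and register linkage are out of scope: the package consumes a
  pre-computed continuous score or ready-made labels.
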