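# Methods

## Stage 1: Poisson regression of daily mortality on temperature

For one region with daily death counts `Y_t`, daily mean/max/min
temperature, relative humidity `rh_t` and calendar date, the model is

```
Y_t ~ Poisson(mu_t)
log mu_t = alpha + sum_k beta_k * hinge_k(T) + s(rh_t, 3)
           + s(time_t, 7 df per year) + lambda' * DOW_t
```

**Reference temperatures.** `tau_low` and `tau_high` are the 10th and 90th
percentiles of the region's daily indicator series (numpy's
linear-interpolation percentile convention; configurable). They are
recomputed from the data, never supplied externally.

**Lag strata and hinge terms.** Temperature enters through window means
over lags 1–3, 4–8 and 9–14 days (arithmetic mean within each window; days
without a full 14-day history are dropped, complete-case). The cold model
carries `max(tau_low - T, 0)` on each of the three strata — cold effects
persist up to two weeks — and the heat model a single
`max(T - tau_high, 0)` on the 1–3-day stratum, reflecting the short lag of
heat effects. The reported slope is the **sum** of a side's hinge
coefficients: the log-rate increase for a *sustained* 1 °C exceedance
across the included strata. The sign convention makes positive slopes mean
"risk rises with the exceedance" on both sides. Hinge terms (rather than
subsetting to cold/hot days) keep the smooth terms estimated on all days.

**Smooth terms.** Fixed-df natural cubic regression splines: boundary knots
at the covariate's min/max, interior knots at equally spaced quantiles,
columns centered for identifiability next to the intercept. Humidity gets
3 df; calendar time gets 7 df per year of data (rounded to the nearest
integer, floor 4). Fixing the df makes the model an ordinary GLM — no
penalized smoothness selection. Note that a *natural* spline basis nests
all linear (not all cubic) functions; that is the property the tests
assert. Day of week is dummy-coded with Monday as reference.

**Fitting.** Hand-rolled IRLS for the Poisson log link: convergence when
the relative deviance change drops below 1e-8 (at most 100 iterations,
else an error with the deviance trace); covariance = inverse Fisher
information at the optimum; `AIC = -2 loglik + 2 p`. The linear predictor
is clipped to ±30 during iteration for overflow safety. Rank deficiency is
detected up front by pivoted QR and reported with the dependent columns.
statsmodels' GLM serves as an independent oracle in the tests, and a dense
grid search of the likelihood as a second oracle on small designs.

**Indicator choice.** The full model is fitted once per indicator (mean,
max, min temperature); minimal AIC wins, ties broken mean > max > min.

**Effect scale.** `percent change = (exp(beta) - 1) * 100` per 1 °C beyond
threshold. A negative percent change is floored at 0 and flagged — "no
deleterious effect" is the reference — but the raw slope and its
delta-method standard error (`se(sum) = sqrt(1' Sigma 1)`) are kept for
interval coverage. Cold and heat are fitted on the whole series (not
season-restricted subsets); the hinge terms vanish off-season by
construction.

## Stage 2: risk labels, discretization, Bayesian network

**Labels.** High risk iff percent change >= 1 %/°C (cold) or >= 10 %/°C
(heat); the boundary value is high risk ("10 % or more").

**Discretization.** Supervised recursive entropy-minimization with the
Fayyad–Irani MDL stopping rule; candidate cuts at boundary midpoints
between class-label changes (so the induced partition is invariant to
strictly increasing transforms). If MDL rejects every cut, a single median
cut is the fallback. Automatic cut lists use the half-open `[a, b)`
convention with boundary values going to the upper state. A manual scheme
can quote printed intervals verbatim — bracket types like `[5.18, 5.25]` /
`(5.25, 12.31]` are honored exactly — which is the faithful path when
reproducing a published set of splits. Categorical factors (climatic zone)
pass through.

**Structure learning.** Simulated annealing over single-edge moves
(add/delete/reverse, drawn uniformly among acyclicity-preserving moves,
with optional white/blacklists). Score: BIC,
`sum_i [loglik_i - (log n)/2 * (r_i - 1) q_i]`, decomposable so moves
re-score only the affected families (cached). Better candidates are always
accepted, worse ones with probability `exp(delta/T)`; the best DAG ever
visited is returned, so the result never scores below the initial graph.
Schedule defaults: initial temperature 1.0, geometric cooling 0.995, 50
moves per temperature, stop at 1e-3, 20,000-iteration cap, explicit seed —
reliable convergence in seconds on the <= 12-node problems here. The score
is a design choice (the standard decomposable one for this search); BDeu
could be slotted in via the same family-score interface.

**Parameters and inference.** CPTs by
`(N(s,c) + a) / (N(c) + a r_i)` with Laplace `a = 1` by default — with ~26
training rows, zero-count cells are the norm — and uniform rows for unseen
parent configurations. All inference (joint, marginal conditional tables
`P(target | factor)`, posteriors) is exact enumeration over full
assignments; at <= 11 nodes with 2–3 states this is instant and removes an
approximation layer. Marginal tables are computed from the fitted network
(not as empirical two-way frequencies; both views exist, network-based is
the default and what the report prints). Prediction is posterior argmax
with ties resolved to the earliest state in the node's state order; risk
nodes list `low_risk` first, so ties are conservative.

**Cross-validation.** Stratified seeded 2-fold split (per-class shuffle and
halve; odd remainders go to the currently smaller fold, so class
proportions and fold sizes are balanced to within one region). Structure
and parameters are relearned per training fold; every region is predicted
exactly once. `pd = TP/(TP+FN)`, `pf = FP/(FP+TN)`, accuracy =
proportion correct — identical for both states by construction. Metrics
are pooled over the two folds' confusion matrices by default; per-fold
averaging is available behind `aggregation="per_fold"` (published 2-fold
tables are sometimes only consistent with one or the other — a pooled
integer matrix cannot produce every printed value). Zero-denominator
metrics are reported as missing, never as 0.

## Exposure construction

Station observations are interpolated to the centroids of a regular
lon/lat grid by inverse-distance weighting — `w_i = d_i^(-power)`, power 2
by default, all stations contributing (no search radius), great-circle
(haversine) distances in km — and averaged (unweighted) over each region's
grid cells. A target coincident with a station reproduces the station
value exactly. Default grid resolution 0.1° (the pipeline uses 0.5° for
speed); polygons rasterize by centroid-in-polygon membership. Stations
missing a value on a day drop out of that day's weights; a day with no
reporting station raises an error naming the date.

## The synthetic world

`tempmort.synth` emulates the study's data-generating structure with a
single seeded random stream forked per sub-generator by stable labels
(adding stations does not perturb mortality draws):

* **Weather** — per-station daily mean temperature = regional mean (18 °C)
  + 10 °C seasonal sinusoid + station offset (sd 1.5 °C) + daily noise
  (sd 2 °C); max/min are the mean ± positive half-ranges (mean 4 °C, sd
  2.5 °C — the day-to-day diurnal-range variability is what makes max/min
  imperfect surrogates of the mean, so indicator selection has something to
  find); humidity is a clipped seasonal sinusoid.
* **Mortality** — Poisson with log-rate = log(baseline 5/day) + cold/heat
  effects + log day-of-week factor (mild, 0.97–1.05) + a small smooth
  humidity bump (3 % peak). The temperature effects multiply, by default,
  the *same* lag-stratum hinge exposures the analysis model estimates
  (cold: the mean of the three stratum hinges, so a sustained 1 °C
  exceedance raises the log-rate by exactly `beta_cold_true`, matching the
  summed-coefficient estimand). A current-day-hinge mode
  (`temperature_exposure="current"`) exists; with a seasonal-sinusoid
  temperature the 90th-percentile exceedance range is only ~5 % of the
  amplitude, so a current-day truth is badly attenuated through a lagged
  analysis model — the matched default is what makes parameter recovery a
  meaningful test. No extra seasonal baseline by default (the smooths then
  face a known truth); a sinusoidal confounder can be switched on to test
  confounder control. Default slopes: ln 1.01 (cold), ln 1.10 (heat),
  mirroring the 1 %/10 % label thresholds.
* **Factors** — one ancestral sample per region from a small known network
  over the ten factors plus binary cold/heat risk labels. The default
  truth has urbanization driving the economic block and gives the risk
  labels the same direct parents and orientations the two published
  networks report (cold: education, %65+, %women; heat: hospital beds,
  %industry, %women), with overall high-risk rates near 9/26 and 7/26.
  Continuous factor values are drawn uniformly within per-state intervals
  (numeric ranges follow the published summaries), so supervised
  discretization can rediscover the state boundaries.
* **Pipeline coupling** — in the end-to-end pipeline each region's true
  slopes are set by its sampled risk labels (cold: 0.2 % vs 2.5 %/°C;
  heat: 4 % vs 15 %/°C, straddling the 1 %/10 % thresholds), so measured
  labels approximate the sampled ones with realistic misclassification.

What the generator does **not** emulate: spatial autocorrelation beyond the
station offset, real climate normals or census marginals, reporting
artifacts, overdispersion, or air-pollution confounding. Passing tests
therefore demonstrate correctness of the estimators under the stated model,
not robustness to those real-data features.

## Problem sizes and numerical choices

The recovery studies use 4-year worlds at 5 deaths/day (the study's scale:
~26 regions, 4 years): 100 replicates for the mean recovered heat effect,
200 for Wald coverage. Structure recovery uses 5,000 samples of a 3-node
chain over 20 seeds; CPT round-trips use 50,000 samples; inference oracles
enumerate models with <= 12 total states; IDW bounds are fuzzed over 1,000
random configurations. The full pipeline runs 26 regions over 2–4 years in
seconds to tens of seconds.

Degenerate inputs: constant temperature series give
`tau_low = tau_high` (hinges inactive); spline construction raises on too
few distinct values; all-zero hinge columns surface as a rank error at fit
time; empty region masks and date gaps raise named errors.

## Known limitations

* No overdispersion/quasi-Poisson correction: standard errors are exact
  only under the Poisson assumption (which the generator satisfies).
* The calendar-time spline absorbs part of the seasonal temperature signal;
  single-region heat estimates are mildly attenuated (visible as a few
  tenths of a point in the recovery study) — an inherent feature of this
  model family, not a defect of the fit.
* Structure learning from 26 rows is weakly identified; the learned DAGs
  and CV metrics on the 26-region pipeline are honest small-sample results
  and vary with the seed.
* The cli surface is the importable API plus `examples/`; there is no shell
  entry point.
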