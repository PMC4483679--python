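# tempmort

Two-stage analysis of temperature-related cardiovascular mortality, built as
a reusable, fully synthetic-testable pipeline:

1. **Per-region effect estimation.** For each region, a Poisson regression
   with smooth terms models the daily cardiovascular death count
   `Y_t`:

   ```
   log E[Y_t] = α + Σ_k β_k · hinge_k(T) + s(rh_t, 3) + s(time_t, 7/yr) + λ'·DOW_t
   ```

   Temperature enters through hinge exceedances beyond region-specific
   reference values — the 10th percentile of daily mean temperature for
   cold, the 90th for heat — applied to stratified lag variables (window
   means over lags 1–3, 4–8 and 9–14 days; all three strata for cold, the
   1–3-day stratum for heat). Humidity and calendar time get fixed-df
   natural cubic regression splines, so the fit is a plain Poisson GLM
   solved by IRLS. Effects are reported as the **percent change** in
   mortality per 1 °C beyond threshold, `(exp(β) − 1) × 100`, with negative
   estimates floored at 0.

2. **Explaining inter-region variation.** Regions are labeled *high risk*
   when their percent change is at least 1 %/°C (cold) or 10 %/°C (heat).
   Continuous socioeconomic/demographic factors (hospital beds, education,
   % women, % over 65, occupation mix, …) are discretized — supervised
   entropy/MDL splits or manual printed intervals — and a discrete Bayesian
   network over factors + risk label is learned by simulated annealing
   (BIC score, single-edge moves). The joint factorizes as
   `P(x) = Π_i P(x_i | pa(x_i))`; marginal conditional tables
   `P(risk | factor)` and posteriors are computed by exact enumeration.
   The classifier is scored by 2-fold cross-validation with *pd*
   (probability of detection), *pf* (probability of false alarm) and
   accuracy.

The real surveillance, weather-station and census inputs of such studies
are restricted, so `tempmort.synth` generates complete study worlds with
known ground truth (true effect slopes, true network, true labels); every
stage is tested against that truth or an independent oracle.

Audience: epidemiologists and biostatisticians prototyping
temperature–mortality analyses, and anyone needing a compact, tested
reference implementation of the GAM + Bayesian-network two-stage design.

## Worked example

```python
import numpy as np
from tempmort import synth, gam

cfg = synth.WorldConfig(seed=11, beta_cold_true=0.0,
                        beta_heat_true=float(np.log(1.10)))  # +10 %/degC truth
weather = synth.generate_region_weather(cfg)
series = synth.generate_mortality(weather, cfg)

est = gam.estimate_effects(series, "heat", region_id="R00")
print(est.percent_change, est.wald_interval())
```

Running `python examples/03_temperature_mortality_gam.py` (which does the
above for both sides) prints:

```
reference temperatures: tau_low 8.52 degC (10th pct), tau_high 27.77 degC (90th pct)
heat: percent change 6.73%/degC (slope +0.0652, 95% CI [-0.0173, +0.1476], floored=False)
cold: percent change 10.99%/degC (slope +0.1043, 95% CI [-0.1039, +0.3125], floored=False)
truth: heat +10%/degC, cold 0%/degC
```

One 4-year region at 5 deaths/day is a noisy instrument: the heat estimate
(6.7 %) sits well inside its interval around the true 10 %, and the wide
cold interval correctly includes the true 0. Averaged over 100 seeded
replicates the heat estimator recovers 10 % to within a fraction of a point
(see below). The other scripts in `examples/` walk through station
interpolation, discretization, network learning and the full 26-region
pipeline (`tempmort.evaluate.run_pipeline`), each printing what it computes
and what the numbers mean.

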