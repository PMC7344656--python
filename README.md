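# carisk

Small-area analysis of primary-care access and cardiometabolic risk.

`carisk` is for epidemiologists and health-geography researchers who want to
ask: *does geographic access to primary care explain between-area variation
in cardiometabolic risk factors (CMRFs)?* It implements the full analytical
chain as a tested Python library plus CLI:

* **2SFCA access index** — the two-step floating catchment area method.
  Step 1: each provider site *j* gets a supply-to-demand ratio
  `R_j = S_j / Σ_i p_i` over the areas whose centroids lie within the buffer
  radius d0 (S_j = GP head count, p_i = adult population). Step 2: each area
  gets `A_i = Σ_j R_j` over its reachable sites. Includes the 1/16/30 km
  buffer-coverage sensitivity report.
* **Cohort construction** — most-recent-test selection inside a study
  window, exclusion of incomplete records with a per-reason log, and
  guideline dichotomization of seven CMRFs (fasting glucose, HbA1c, total
  cholesterol, HDL, albumin–creatinine ratio, eGFR, BMI).
* **Multilevel logistic models** — persons nested in areas with a Gaussian
  random intercept, `logit P(y=1|u_a) = x'β + u_a`, `u_a ~ N(0, τ²)`,
  fitted by maximum likelihood with adaptive Gauss–Hermite quadrature
  (validated against dense-grid integration and lme4's `glmer`). Five
  nested models per CMRF: null (M1), +access (M2), sex+age (M3), +area
  disadvantage (M4), +access (M5), with Wald odds ratios per SD, AIC, and
  likelihood-ratio tests.
* **Contextual-effect statistics** — latent-variable ICC
  `τ²/(τ² + π²/3)`, median odds ratio `exp(√(2τ²)·Φ⁻¹(0.75))`,
  proportional change in variance against the null model, and the variance
  share explained by access alone (M4 vs M5).
* **Synthetic regions** — a seeded generator of areas, provider sites,
  persons and outcomes with the statistical structure the analysis assumes,
  so every stage is testable without restricted health data.

See `docs/methods.md` for the model details and design choices.

## Worked example

```python
import carisk as ck
from carisk.access import AccessConfig, provider_ratios, access_index
from carisk.pipeline import run_ladder

# a seeded synthetic region: 300 areas, 30 provider sites
cfg = ck.RegionConfig(n_areas=300, pop_range=(100, 100), n_provider_sites=30,
                      gp_total=90, region_extent=(60.0, 60.0),
                      irsd_missing_frac=0.0, seed=2024)
areas = ck.generate_areas(cfg)
providers = ck.generate_providers(cfg, areas)

# 2SFCA at a 30 km buffer
acfg = AccessConfig(buffer_km=30.0)
providers = provider_ratios(providers, areas, acfg)
areas = access_index(areas, providers, acfg)

# simulate an obesity-like outcome and fit the nested ladder
params = ck.OutcomeModelParams(
    intercept=-1.386, beta_age=ck.DEFAULT_OUTCOME_PARAMS["BMI"].beta_age,
    beta_irsd=-0.21, beta_access=-0.09, tau2=0.1)
records = ck.generate_persons(areas, seed=2024, cmrfs=("BMI",),
                              sampling_fraction=1.0, repeat_rate=0.0)
records = ck.simulate_outcomes(records, areas, params, seed=1)

run = run_ladder(records, areas, quadrature_order=15)
print(run.summary[["model", "tau2", "icc_pct", "mor", "pcv_pct"]]
      .round(3).to_string(index=False))
```

prints (seed 2024/1, 30 000 persons):

```
model  tau2  icc_pct   mor  pcv_pct
   M1 0.163    4.709 1.469      NaN
   M2 0.152    4.407 1.450   -6.717
   M3 0.171    4.942 1.484    5.208
   M4 0.121    3.554 1.394  -25.428
   M5 0.113    3.320 1.378  -30.502
```

Read: the null model puts ~4.7% of latent outcome variance between areas
(MOR 1.47 — the median odds shift when moving to a higher-risk area).
Adjusting for sex and age slightly inflates the area variance, area
disadvantage explains ~25% of it, and adding the access index extends the
reduction to ~31%. The M5 access row of `run.or_tables["M5"]` reads

```
    term   beta    se    or  ci_low  ci_high  p_value
access_z -0.092 0.023 0.912   0.871    0.955      0.0
```

recovering the generating effect exp(−0.09) ≈ 0.914 per SD within sampling
error.

The same study runs from the shell:

```bash
carisk -v study --config run.yaml --seed 1 --out results/
```

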