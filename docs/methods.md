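# Methods

`carisk` studies whether geographic access to primary care explains
between-area variation in cardiometabolic risk factors (CMRFs). It couples a
spatial accessibility index with a multilevel (persons-in-areas) logistic
analysis, and ships a synthetic-region generator so the full pipeline is
testable end to end without any restricted health data.

## Spatial access: two-step floating catchment area (2SFCA)

Areas are represented by their population-weighted centroids on a projected
plane (coordinates in km); provider sites carry a GP head count `S_j`.

* **Step 1** — for each site `j`, the supply-to-demand ratio
  `R_j = S_j / Σ_i p_i`, summing the adult population `p_i` of every area
  whose centroid lies within the buffer radius `d0` of the site.
* **Step 2** — for each area `i`, the access index `A_i = Σ_j R_j` over all
  sites within `d0` of the area centroid.

Design choices, fixed for reproducibility:

* distances are straight-line Euclidean (no road network or travel time —
  a recognised limitation of radial-buffer access measures);
* the catchment boundary is **inclusive** (`d ≤ d0`);
* default `d0 = 30 km`, with a coverage sensitivity report at 1/16/30 km
  (the share of area centroids that can reach at least one site) to justify
  the working radius for a given region;
* sites whose catchment is empty or has zero population have an undefined
  `R_j`; they are excluded from step 2 and logged. Setting `R_j = 0` would
  give identical sums but hide data problems.
* `p_i` is the *adult* population; `A_i` is kept continuous. A per-1000
  reporting scale is provided for display only — models consume the
  standardized index, so the scale cancels.

Useful identity (tested): `Σ_i p_i · A_i = Σ_j S_j` over sites with a
defined ratio, because each `R_j` is redistributed exactly once over the
population that generated its denominator.

## Cohort construction

Raw test records → one analysis record per person per CMRF:

1. keep the most recent test inside the study window (default
   2012-01-01..2017-12-31); ties on the date break on the highest record id
   (deterministic and auditable);
2. exclude records with incomplete details — missing sex, age band, area
   link, usable value, or an area without a disadvantage score — with a
   per-reason count log (listwise exclusion);
3. dichotomize values by guideline cut-points with the printed boundary
   semantics: FBSL ≥ 7.0 mmol/L, HbA1c > 7.5 %, TC ≥ 5.5 mmol/L,
   HDL < 1 mmol/L, ACR ≥ 30, eGFR < 60 mL/min/1.73 m², BMI ≥ 30 kg/m².
   Boundary cases matter: FBSL 7.0 *is* higher risk; HbA1c 7.5, HDL 1.0 and
   eGFR 60 are *not*.

## The multilevel model and its estimation

For person *i* in area *a*, with `y ∈ {0,1}`:

    logit P(y=1 | u_a) = x' β + u_a,   u_a ~ N(0, τ²)

Fixed effects are drawn from: intercept; male indicator (female reference);
six age-band indicators (18-29 reference); and the area-level disadvantage
score and access index as mean-centred per-SD covariates. Standardization
constants are the **unweighted area-level** mean/SD, computed once per
analysis dataset and shared by every model in a ladder — so odds ratios are
per SD of the area distribution and comparable across models. (Whether
record-level SDs should be used instead is a genuinely open choice; the
area-level convention is recorded in every fit's metadata.)

The marginal likelihood integrates the random intercept out per area. Each
1-D integral is approximated by **adaptive Gauss–Hermite quadrature**:
a damped Newton iteration (vectorized across areas; the integrand is
log-concave, convergence tolerance 1e-11 on the step) finds the conditional
mode and curvature, the GH rule (default 15 nodes, odd so the mode itself is
a node) is recentred and rescaled there, and the node sum is accumulated by
log-sum-exp. At σ = 0 the likelihood is evaluated exactly as the ordinary
logistic log-likelihood. Accuracy is pinned by two oracles in the test
suite: dense trapezoid integration (agreement to 1e-6 on small fixtures) and
lme4's `glmer` at the same node count (agreement to ~1e-3 in log-likelihood
and ~5e-3 in coefficients on a 1800-row fixture).

Optimization is L-BFGS-B over `(β, log σ)` — the log parameterization keeps
σ positive without constraints — starting from the ordinary logistic fit
with σ = 0.2. Convergence: relative objective change below 1e-11 and
projected-gradient norm below 1e-6, max 500 iterations. σ is floored at
1e-6; fits ending at σ ≤ 1e-4 are reported as boundary fits with τ² = 0,
and their fixed-effect SEs fall back to the ordinary logistic information.
Standard errors otherwise come from the inverse of a central
finite-difference Hessian at the optimum; Wald 95% intervals and p-values
accompany the exponentiated coefficients. AIC counts `|β| + 1` parameters
(τ² included), matching the usual mixed-model convention.

## The nested model ladder

Per CMRF, five models share one dataset and one set of standardization
constants:

| model | fixed effects |
|-------|---------------|
| M1 | intercept (null) |
| M2 | + access |
| M3 | intercept + sex + age |
| M4 | M3 + disadvantage |
| M5 | M4 + access |

Likelihood-ratio tests follow the available nesting arrows (M2 is not
nested in M3): M1→M2, M1→M3, M3→M4, M4→M5, each checked for strict
parameter-set containment before testing. Sequential fits warm-start from
the previous model's shared coefficients.

## Contextual-effect statistics

From each fitted τ²:

* **latent-variable ICC** = τ² / (τ² + π²/3): the logistic threshold model
  assigns residual variance π²/3, so this is the share of latent-scale
  variance between areas;
* **median odds ratio** MOR = exp(√(2τ²)·Φ⁻¹(0.75)): the median of the odds
  ratios comparing two identical persons from a higher- vs lower-risk area
  (≥ 1 by construction, 1 = no area effect);
* **PCV** = 100·(τ²_model − τ²_ref)/τ²_ref against the null model
  (negative = variance explained; positive inflation is possible and real —
  compositional adjustment can uncover between-area heterogeneity);
* **variance explained by access alone** = the same contrast between the
  fully adjusted models without (M4) and with (M5) the access term.

Machine outputs keep unrounded values; display tables round ICC to 1 d.p.
and MOR to 2–3 d.p. One printed-value caveat: published MOR/ICC tables are
computed from unrounded fitted variances, so re-deriving them from the
*printed* τ² can differ by one unit in the last digit (e.g. τ² printed as
0.101 gives MOR 1.354 → 1.35, where 1.36 was printed). The test suite
pins exact round-trips where the printed arithmetic is self-consistent and
one-last-digit agreement elsewhere.

## Synthetic regions: what they emulate and what they do not

`RegionConfig` defaults describe the study frame the analysis is designed
for: 980 areas of 200–800 adults (uniform), a 110 × 51 km planar frame,
165 provider sites with 611 GPs placed with probability proportional to
area population (~1 km jitter, ≥ 1 GP per site), and disadvantage scores
N(976.7, 98.6²) with ~1% missing completely at random. Tested persons are a
configurable sampling fraction of each area's adults (default 0.65, male
share 0.48, an older-skewed age mix); each person gets one record per CMRF
with a uniform in-window date, plus repeat tests at a 10% rate so
most-recent selection has work to do.

Outcomes are simulated from the same random-intercept model the fitter
assumes — one `u_a ~ N(0, τ²)` per area (per CMRF), one Bernoulli draw per
person × CMRF (repeats share it). Per-CMRF default generating parameters
are anchored to published adjusted-model estimates (e.g. obesity:
intercept log 0.25, disadvantage −0.20/SD, access −0.07/SD, τ² = 0.062);
prevalences span the observed 4–34% range. Everything is reproducible
bit-for-bit from a single integer seed.

Deliberately **not** emulated: realistic coastline/road geometry, travel
time, spatially autocorrelated disadvantage, provider-choice behaviour,
ethnicity or blood pressure, and any model misspecification (outcomes are
generated by the fitted family). Passing recovery tests therefore
demonstrates correctness of the estimation machinery, not robustness to
real-data violations of the model.

## Problem sizes used in the shipped checks

The recovery study uses 300 areas × 100 persons with 20 replicate outcome
draws on one fixed region (generating τ² = 0.1, access −0.09/SD,
disadvantage −0.21/SD) — large enough that the Monte-Carlo SE of the mean
estimate separates signal from bias, small enough to run routinely. The
type-I-error study of the M4→M5 LRT uses 120 areas × 40 persons, 200
replicates, 7 quadrature nodes (the LRT contrasts two likelihoods computed
with the same rule, so modest node counts suffice; the node-convergence
test shows order 7 vs 21 differs by < 1e-4 in log-likelihood at these
sizes). Both were chosen as routine-verification sizes; the machinery runs
unchanged at census scale.

## Known limitations

* Radial-buffer 2SFCA ignores travel impedance inside the catchment; no
  distance-decay (enhanced 2SFCA) variant is provided.
* Single random intercept only: no random slopes, crossed levels, or
  three-level nesting.
* Wald intervals for ORs; no profile or bootstrap intervals, and no
  interval estimates for ICC/MOR.
* The latent-variable ICC is one of several ICC estimands for binary
  outcomes; linearization or simulation approaches would give different
  numbers.
* PCV can exceed ±100% and is unstable when the reference variance is near
  zero; the reference must be strictly positive.
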