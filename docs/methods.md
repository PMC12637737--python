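# Methods

This note records the model, the calibration of the shipped synthetic
parameter set, the numerical conventions, and the limits of what the
package's tests demonstrate.

## Simulation structure

Agents are ART initiators entering in calendar years 2013–2017, followed for
seven years from initiation on an annual cycle. The model deliberately
isolates one pathway — BMI change after ART initiation → incident type 2
diabetes diagnosis — and omits everything else a full multimorbidity model
would carry (other comorbidities, CD4 dynamics, care disengagement, ART
regimen effects). Entry year therefore has no effect on outcomes; it is
retained for cohort accounting only.

Per subgroup and entry year the agent count is Poisson with mean
`scale × initiators_per_year`, so the population size itself carries
sampling uncertainty, matching the way published cohort sizes are reported
with uncertainty ranges. `exact_counts=True` replaces Poisson by rounded
means for deterministic tests.

**Common random numbers.** Each agent receives 19 uniform draws at
generation time, consumed in a fixed order: gain indicator, gain magnitude,
loss magnitude, enrollment, adherence, seven annual diabetes draws, seven
annual mortality draws. Both trial arms replay the same draws; the arms can
differ only through the BMI-dependent term of the hazard. Consequences used
by the tests: arms are identical record-for-record when effectiveness is 0
or when the hazard has no BMI pathway, and averted counts are non-negative
agent-by-agent whenever the BMI coefficients are monotone.

## Baseline distributions

* **Age**: only the median and a 95% range are available per subgroup. We
  use a two-piece folded-normal ("split-normal") distribution: with
  probability ½ the draw is median − σ_l·|Z|, otherwise median + σ_r·|Z|,
  with σ set so the 2.5th/97.5th percentiles match the published range;
  values are clipped to [18, 85]. This is the minimal shape that reproduces
  an asymmetric three-quantile summary while keeping the median exact.
* **BMI category**: published shares are used directly for underweight
  (<18.5) and the eligible band (18.5–<30); the obese share is defined as
  the residual 1 − p_uw − p_mid because the published three shares are
  rounded and sum to 0.98–0.99 in most subgroups. The underweight and
  eligible-band shares are the ones the published eligibility products rest
  on, so they are kept verbatim; overall baseline obesity comes out ≈20%
  versus the published (rounded) 19%, within one point.
* **Within-category BMI**: underweight uniform on [16, 18.5), normal
  uniform on [18.5, 25), obese uniform on [30, 40). The overweight band
  [25, 30) uses a triangular density rising linearly toward 30. A uniform
  overweight band cannot reconcile three published marginals simultaneously
  (66% of eligible agents gaining, median gain ≈1.0 kg/m² with a 97.5th
  percentile ≈2.4, and 12% of eligible agents reaching obesity by month 24):
  under uniformity the implied obesity conversion is ≈7%, and inflating the
  gain scales to force 12% pushes the median gain to ≈1.6. Concentrating
  overweight mass toward the obesity cut — which is also what a
  right-shifted population BMI distribution looks like near 30 — reconciles
  all three at the published gain quantiles. The share of the eligible band
  that is overweight (`overweight_share` ≈ 0.42) is a single common value
  calibrated so the pooled median positive gain equals 1.01 kg/m².
* **Prevalent diabetes** is sampled independently of BMI category within
  subgroup; the published eligible fractions are consistent with this
  independence product (overall 0.77 × 0.95 ≈ 0.73).

## 24-month BMI change

With probability p_gain (per subgroup) the change is a log-normal gain
`exp(μ_g + σZ)`; otherwise a non-positive half-normal loss `−s·|Z|` with
s = 0.75 kg/m². σ = 0.46 is common to all subgroups and chosen so the pooled
2.5th/97.5th gain percentiles sit near the published 0.39/2.38 around a
median of 1.01. The per-subgroup scales μ_g are calibrated by bisection
(deterministic quadrature, no Monte Carlo) so each subgroup's probability of
reaching BMI ≥ 30 by month 24 among eligible agents matches its published
share. BMI is interpolated linearly within years 1–2 and held constant from
month 24 to the horizon; obesity conversion is evaluated at month 24.

The intervention transform is `Δ' = min(Δ, 0)` for enrolled-and-adherent
agents: decreases are untouched, increases removed. It is idempotent and
never raises BMI. Effectiveness is all-or-nothing per agent (a Bernoulli
adherence draw), which makes the expected impact multiplier exactly
coverage × effectiveness — the analytic oracle used for the scenario grid.

## Hazard, mortality, person-time

Annual diagnosis probability: logistic in subgroup intercept, decadal age
band, BMI category (normal as reference), and β_ΔBMI × cumulative positive
gain. Fixed a-priori coefficients (log-odds): β_age = (−0.3, 0, 0.6, 1.0,
1.3, 1.5, 1.6) for <20 through 70+, β_BMI = (−0.3, 0, 0.5, 1.0) for
underweight/normal/overweight/obese — both encode the qualitative pattern
that risk rises with age and baseline BMI; no published coefficient values
exist to match. The hazard is evaluated at the year-start state.

Within a year, death is evaluated before diagnosis: an agent whose mortality
draw fires that year cannot be diagnosed in it (a conservative, documented
tie-break). Diagnosed agents continue to accrue person-time until death or
the 7-year horizon; a death in year t contributes t − 0.5 person-years
(mid-year convention). `person_years(..., censor_at_diagnosis=True)` offers
the conventional at-risk alternative for comparison, but all headline rates
use death-only censoring, which is what the published diagnosis-count /
rate pair implies.

Mortality is a flat annual probability per decadal age band, identical
across subgroups: (0.0015, 0.0015, 0.002, 0.004, 0.006, 0.010, 0.020) for
<20 … 70+. This yields ≈97% 7-year survival, so mortality acts purely as the
light censoring mechanism it is in the source analysis (which reports no
death counts); it is synthetic and deliberately small relative to the
diabetes effects.

## Calibration of the shipped parameter set

`scripts/build_default_params.py` performs, in order:

1. `overweight_share` and the per-subgroup gain scales μ_g (bisection inside
   bisection, quadrature objective) as above.
2. Joint calibration of β_ΔBMI and the 15 intercepts: for each trial value
   of β_ΔBMI, every subgroup intercept is re-fit by Brent root-finding so a
   fixed 20,000-agent eligible cohort's simulated control-arm rate hits its
   target (2% relative tolerance); β_ΔBMI is then bisected until the pooled
   RRR of a 30-replicate 1/10-scale run falls at ≈18.5%, the centre of the
   published 16–21% band. The root-finding objective is a step function of
   the intercept but monotone because the cohort and its draws are frozen
   (pure CRN), which is what makes Brent's method applicable.

Rate targets: published subgroup values are used verbatim; two further
subgroups are anchored to published diagnosis counts; the remaining eight
are interpolated between neighbouring published values and then adjusted as
a group so the person-year-weighted pooled rate reproduces the published
10.7 per 1,000 person-years. The `authoritative` flag in `bmisim.targets`
separates published anchors from interpolations.

Calibration-produced quantities (intercepts, β_ΔBMI = 0.0938, μ_g,
overweight_share) are recorded in the parameter file with a provenance
string; they are calibration products, not published estimates.

## Sensitivity analysis

`perturb_parameters` scales five blocks by independent uniform factors in
[1−m, 1+m] (default m = 0.2): initiator counts, baseline BMI (a
multiplicative scale on the continuous BMI value, categories recomputed
downstream), 24-month BMI change (scale on the signed magnitude), prevalent
diabetes (clamped to [0,1]), and the annual diagnosis probability (clamped
to [0,1]). The two prevalence blocks a full multi-cohort model would
distinguish collapse to one here because only 2013–2017 initiators exist.
`run_psa` keeps the trial seeds fixed across draws so outcome variation
across draws reflects the factors alone, and reads sensitivity off the
top-versus-bottom factor decile contrast, one block at a time. Default PSA
problem size is 10 replicates per draw at 1/10 scale — a desk-scale
reduction of the full design.

## Problem sizes and numerical conventions

* Reference end-to-end run (tests, acceptance script, README example):
  100 replicates at scale 0.1, ≈12,600 eligible agents per replicate,
  seeds base_seed + replicate index; medians of pooled measures are stable
  to ≈±0.5% across base seeds at this size.
* Calibration: 20,000 eligible agents per subgroup (40,000 in the
  parameter-recovery tests), Brent xtol 10⁻⁶, 2% relative rate tolerance.
* Quantiles: linear-interpolation definition (`numpy.percentile` default);
  95% UR = 2.5th–97.5th percentiles across replicates.
* Report rounding mirrors the published conventions — rates to one decimal,
  percentages to integers, averted counts to the nearest ten, population
  sizes to the nearest hundred; machine outputs always keep raw values.
* CRN draws are clipped to (10⁻¹², 1−10⁻¹²); annual probabilities to
  ≤ 1−10⁻¹² after the sensitivity scale factor.
* Degenerate inputs: empty year ranges, non-positive scale, probabilities
  outside [0,1], all-zero pooling weights, empty replicate vectors and
  non-bracketing calibration intervals all raise immediately;
  `validate_parameters` reports (rather than raises) every range violation
  with its field and subgroup.

## What the synthetic generator does and does not emulate

It reproduces the published *marginal* structure: subgroup sizes and their
sampling variability, age medians and 95% ranges, category shares,
gain/obesity-conversion shares, and subgroup control-arm rates. It does not
reproduce joint structure the source data would carry — age×BMI correlation
at entry, within-subgroup heterogeneity in gain propensity, regimen effects,
secular trends across entry years, or mortality differentials by subgroup.
Passing tests therefore demonstrate that the simulation machinery (CRN
pairing, person-time accounting, pooling, calibration, uncertainty
aggregation) is correct and that the calibrated model reproduces the
published headline outcomes; they are not evidence about any real cohort
beyond those marginals.

Known limitations: subgroup-level intervention effects (relative reductions,
subgroup NNT ordering) depend on the single common β_ΔBMI and the synthetic
within-band BMI shapes, so they match the published pattern only loosely;
the 70+ age band is sparse and its stratified estimates are noisy; and the
choice to evaluate death before diagnosis within a year slightly lowers
incidence relative to the opposite ordering (≈0.4% of annual mortality, far
below Monte-Carlo noise at the reference size).
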