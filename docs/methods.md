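# Methods

## Model

`fractrans` implements a progressive five-state continuous-time Markov
model of bone health: no fracture (1), initial fracture (2), second
fracture (3), third or further fracture (4), and death (5, absorbing).
Seven transitions are allowed — to the next fracture state, or to death
from any live state — so the transition graph is acyclic and the
transition-probability matrix is upper triangular at every horizon.

Each transition (r, s) has intensity q_rs(z) = exp(α_rs + β_rsᵀ z),
proportional in the covariates. The generator Q(z) collects these rates
with diagonal −Σ_s q_rs; P(t) = expm(tQ) (scaling-and-squaring with
Padé approximation via `scipy.linalg.expm`; the triangular structure
would admit an eigendecomposition, but the general algorithm is kept
for robustness against near-confluent eigenvalues). Expected sojourn
time in a transient state is −1/q_rr; a state with no exit intensity is
reported as an infinite sojourn rather than an error, and the absorbing
state's sojourn is undefined (NaN).

### Assumptions

- **Markov and time-homogeneous within a state occupancy**: intensities
  are constant given the covariates; there is no sojourn-duration
  dependence (no semi-Markov effects) and no frailty.
- **Age as a time-variant covariate, refreshed at state entry**: the age
  covariate takes the value at entry to the current state and is held
  constant until the next transition. This avoids immortal-time bias in
  later states (subjects must survive to reach them). Prediction
  horizons that cross a state entry are handled by chaining per-segment
  matrix exponentials (`piecewise_transition_probability`).
- **Progressivity**: no recovery transitions; a fracture count never
  decreases.

## Covariate coding

The published hazard ratios for continuous risk factors do not state
their units, so the coding is explicit and configurable
(`CovariateCoding`). Defaults, chosen once: age per **5 years** above
70; femoral-neck BMD T-score per **1 SD below −1.5** (so a positive
coefficient means lower bone density increases risk); BMI per
**5 kg/m²** above 26.6; binaries 0/1 with 0 = reference. The reference
profile (the "typical" individual: age 70, T-score −1.5, BMI 26.6, no
falls, no prior fracture, no comorbidities) codes to z = 0, so
exp(α_rs) is the typical individual's intensity. Reference per-year
intensities for a typical woman and man, taken from the Dubbo
Osteoporosis Epidemiology Study estimates, ship as
`TYPICAL_WOMAN_RATES` / `TYPICAL_MAN_RATES` (e.g. first-fracture
intensity 2.7%/y for women, 1.7%/y for men) and serve as simulation
defaults and worked reference profiles.

Sex can be handled two ways, both supported because published tables
are sex-specific while covariate effects come from a joint model:
`fit_mle(mode="stratified")` (default in the pipeline) fits women and
men separately; `mode="single"` with `"male"` in the covariate list
fits one joint model with a sex hazard ratio per transition.

## Likelihoods and fitting

The observational unit is a sojourn record (subject, state, entry,
exit, destination-or-censored, profile at entry). With exactly dated
events the log-likelihood is

Σ_records [ −(Σ_s q_rs(z)) · Δt + log q_rs(z) if the record ends in r→s ],

which separates over transitions into Poisson-regression pieces with
log person-time offsets. `fit_mle` therefore maximises each
transition's block by Newton iterations with analytic gradient and
Hessian, started from the closed-form no-covariate estimate
q̂_rs = n_rs / T_r, with step-halving to keep the iteration ascending;
convergence at 1e-8 on the block log-likelihood. The covariance is the
inverse **analytic** observed information, which is block-diagonal
across transitions — exact where a finite-difference Hessian would be
approximate. Parameter blocks are clipped to |θ| ≤ 30 as a guard
against divergence under complete separation (possible on transitions
with a handful of events); a fit that touches the clip is flagged
non-converged rather than failing silently. Transitions with zero
observed events are boundary-flagged (rate 0) and excluded from
covariance reporting.

The interval-censored (panel) likelihood — fracture states observed
only at periodic visits, death times exact — multiplies
matrix-exponential entries P_rs(Δt) across successive snapshots; a
death interval contributes Σ_k P_rk(Δt) q_k5. It is provided for the
biennial-visit observation scheme (`fit_panel_mle`, joint BFGS,
intended for modest data sizes; covariance blocks are not produced and
CIs are reported unavailable). Exact-time is the default everywhere:
fractures are radiology-dated and deaths registry-dated in the target
study design. Note the two likelihoods are only commensurable on
exactly dated events: an interval-censored fracture contributes a
probability (∝ grid step), not a density, so the fine-grid limit check
in the tests is run on a death-only configuration.

## Risk outputs

- `instantaneous_risk_table`: q_rs(z) × 100 (%/year) with Wald 95% CIs
  on the log scale via the delta method (var(α + βᵀz) = x̃ᵀΣx̃,
  x̃ = (1, z)). CIs for derived quantities (sojourns, P(t)) are not
  currently produced — a known limitation.
- `five_year_matrix`: 100 · expm(hQ); rows sum to 100 within 1e-6.
- `cumulative_mortality_curve`: P_{r5}(t) on a time grid; nondecreasing
  by construction.
- `sojourn_table`: sojourns across a T-score grid (default 0, −1.5,
  −2.5 — normal, osteopenic, osteoporotic bone).
- `skeletal_age`: years lost = log(H)/log(h) with h = 1.1 by default;
  additive in log H, independent of chronological age, negative (years
  gained) for protective H < 1. Per SD of femoral-neck BMD with
  H = 1.16 this is log(1.16)/log(1.1) ≈ 1.56 y (≈1.5–1.6 y).
- `incidence_rate`: events per 1000 person-years with the exact
  (Garwood) Poisson CI from chi-squared quantiles; its exact coverage
  is ≥ the nominal 95% at every rate.

## Synthetic cohorts

The generator emulates the structure of a two-decade population-based
osteoporosis cohort (2046 women, 1205 men aged ≥ 60 by default).

- **Baseline**: entry age truncated normal ≥ 60 (mean 70, SD 7 women /
  6 men); femoral-neck BMD normal (0.81 ± 0.14 women, 0.92 ± 0.15 men,
  g/cm²) converted to T-scores against young-adult references
  (1.00 ± 0.12, 1.04 ± 0.12); BMI normal (26.5 ± 5.1, 26.8 ± 3.9,
  floored at 14); falls (37.9% / 26.3%), prior fracture (17.5% /
  11.5%) and six comorbidities as independent Bernoulli draws at the
  published marginal prevalences (the joint correlation structure is
  not published; independence is the declared simplification).
- **Trajectories**: competing exponential clocks per allowed exit at
  the profile's intensities, age refreshed at each state entry.
  True baseline intensities default to the typical-rate tables; true
  covariate effects are set once as an age gradient (HR 1.67 per 5 y on
  death transitions — the published mortality HR — and 1.35 per 5 y on
  fracture transitions) and a bone-density gradient (HR 1.16 per SD
  lower on death, 1.40 per SD lower on fracture), in line with the
  scale of the published per-transition hazard ratios, whose exact
  per-covariate values are not printed.
- **Follow-up**: entry staggered uniformly over a 5-year recruitment
  window; administrative censoring at the 21-year study end; dropout as
  an independent exponential with median 9 years (the cohort's median
  follow-up, interpreted as the censoring-time distribution — death
  also truncates observation, so realized follow-up is shorter). The
  actual censoring process of the emulated study is not described; this
  is a declared choice.
- **Observation**: `exact` passes event times through; `biennial`
  coarsens fracture states to 2-yearly visits (death exact), which
  loses late-interval fractures — by construction the panel scheme
  never sees more fractures than occurred.

What passing simulation tests do **not** show about real data: real
cohorts have correlated comorbidities, informative dropout, measurement
error in BMD, semi-Markov effects, secular trends and treatment uptake
— none of which the generator produces. Recovery and calibration
results certify the estimator under the model's own assumptions, not
the model's fit to any particular cohort.

## Problem sizes and numerical choices

The test suite uses cohorts of 400–3 251 subjects (25 000–100 000 for
moment and large-sample checks), a 200-replicate recovery study at the
emulated study's size (n = 3 251), and ODE oracles integrated at
rtol 1e-11. Generator row sums are enforced to 1e-10, row-stochasticity
to 1e-8, and the fitter's score to 1e-6 per event. Simultaneous events
are not generated (continuous clocks); in data preparation a fracture
on the day of death orders the fracture first, and a repeated
same-state row is read as censoring. Calibration strata are
sex × 5-year age band (60–90+) × state; the observed exit fraction is
the Kaplan–Meier complement at the horizon (censoring-robust, via
`lifelines`), the prediction is the stratum mean of
1 − exp(−h·Σ_s q_rs(z)), and empty strata are flagged rather than
dropped.

## Known limitations

- No CIs on sojourns or transition probabilities (delta-method CIs
  cover intensities only).
- Panel-mode fitting returns no covariance and is slow beyond a few
  hundred subjects.
- No semi-Markov hazards, no time-varying covariates within a state,
  no multiple imputation of missing bone density, no cause-specific
  mortality — all outside the model's scope.
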