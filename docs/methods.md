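# Methods

This note records the modelling choices, default parameters and known
limitations of the package, in the spirit of a model-documentation page:
what is computed, under what assumptions, and what the tests do and do not
establish.

## Disease model

Nine health states with 25 allowed transitions: hormone-naive entry states
HS1 (non-metastatic or node-only — the M0 subgroup), HS2 (bone metastases)
and HS3 (visceral metastases); castration-resistant states HS4/HS5/HS7
mirroring the same anatomical split, plus HS6 for skeletal-related events
(SREs) after bone metastasis; and two absorbing states, HS8
(prostate-cancer death) and HS9 (other-cause death).  Eleven transitions
connect the alive states; every alive state can reach both death states.

Event classification maps dated clinical events onto this chain.  Two rules
matter: an SRE in a naive non-metastatic patient without a metastasis event
is treated as treatment failure (HS1→HS4, not HS6); and a metastasis in a
naive patient is itself a failure event routed by site (bone→HS5,
visceral→HS7).  Same-day events are ordered metastasis < SRE < failure <
death, which guarantees the resulting chain is valid; this tie-break is the
package's own convention.  An SRE simultaneous with first bone metastasis
lands in HS5, with the next SRE moving to HS6.

## Survival models

Nine model groups partition the 25 transitions: one joint first-event model
(failure-free survival: all exits from HS1–3 to HS4/5/7/8), one joint
other-cause-death model (HS1–7→HS9, covariate = age group only), one joint
model for moves into the worst CRPC state (HS4/5/6→HS7, pooled because such
events are rare), and six single transitions (HS4→HS5, HS5→HS6, and the
four CRPC-to-HS8 moves).

All families share one maximum-likelihood engine with a linear predictor in
the location (log hazard for the exponential): exponential, Weibull (AFT
parameterisation), lognormal, and generalised gamma in the (μ, σ, Q)
convention where Q→0 recovers the lognormal and Q=1 the Weibull (the
lognormal branch is used for |Q| < 1e−5).  The flexible parametric model
works on the log cumulative-odds scale, log((1−S)/S) = s(log t) + xᵀβ, with
s a restricted (natural) cubic spline: boundary knots at the min/max
uncensored log event times, internal knots at equally spaced quantiles;
df=1 reduces exactly to the log-logistic proportional-odds model (verified
against the closed form in tests), and the basis is linear beyond the
boundary knots, giving log-logistic-type tails for extrapolation.  Variances
come from the numerically differentiated observed information; model choice
is by AIC with ties broken by parameter count then a fixed family order.

Destination allocation within the joint first-event model uses a saturated
multinomial (Laplace-smoothed frequencies) on baseline state × arm; the
structural destination sets differ by baseline state, which is why a single
regression across states is not used.

Post-failure models are fitted clock-reset (time since state entry) with
time from randomisation to failure as a covariate; the first-event and
other-cause models run on the randomisation clock.  Event times in the
simulator are drawn by inverse transform on the fitted conditional survival
function (closed-form where available, bracketed root-finding on log time
for the generalised gamma and spline).

The sparse-data concern for M0 patients after progression is handled
structurally: CRPC states HS5–HS7 are shared between subgroups, so their
models are fitted on all occupants (mostly M1-origin patients), and M0
patients entering them inherit those estimates.  HS4 transitions are fitted
on HS4 data directly.

## Utilities

EQ-5D-3L responses are scored with the UK time-trade-off value set, shipped
as a data file (constant 0.081 for any dysfunction, ten level-2/3
decrements, 0.269 when any dimension is at level 3; worst state −0.594) and
replaceable by any CSV with the same terms.  Partially completed
questionnaires are treated as missing.

Missing scores are multiply imputed by chained equations with predictive
mean matching (statsmodels MICEData), separately by randomised arm, with 5
imputations of 30 iterations each; predictors are visit timing, baseline
covariates, health state at the visit and an in-trial death indicator.
PMM means imputed values are donor values, so they stay inside the observed
range.  Utility is zero from death by construction of the accrual (dead
states contribute nothing), not by regression.

The two-part regression handles the ceiling at 1: a logit model for
P(u = 1) and a gamma regression with identity link for the disutility 1−u
when below the ceiling, fitted by working-independence estimating equations
with robust cluster (patient) errors; fits are compared by QIC.  The phrase
sometimes used for the first part ("binomial with log link") conflicts with
a logit specification; logit is the default here and a log-link binomial is
available via `link="log"`.  By default the single best-QIC imputation
feeds the simulator (`fit_best_imputation`), with Rubin-rules pooling
available (`pool_imputations`; pooled covariance = within + (1+1/m)
between).  The treatment effect on quality of life is restricted to the
first year after randomisation via a three-category covariate (first-year
AAP / first-year SOC / later either arm).

## Costs

English NHS perspective, 2017–18 GBP, three categories: investigational
(abiraterone at the £97.68/day list price plus prednisolone), specific
expensive medications (docetaxel, enzalutamide, cabazitaxel, radium; ~20%
list-price reductions applied to the last three), and general disease
management.  Dose imputation rules: missing abiraterone → 1000 mg/day;
missing prednisolone → 5 mg/day with dates copied from the patient's
abiraterone record; other drugs → modal observed dose, else the listed
default.  Records are costed onto 42-day cycles by exact half-open-interval
day overlap.

General-management cycle costs are right-skewed, so the regression is split
at a £1,500-per-cycle boundary (configurable): a logit for exceeding the
boundary, a generalised-gamma regression below it (reusing the survival ML
engine on uncensored amounts; its mean is exp(μ) times a shape constant
computed by numerical integration), and a Gaussian model above it with
predictions floored at the boundary.  Strata are arm × health state with a
pooled fallback for small strata.  Specific-medication costs are empirical
means per health state and time-in-state band (<1 year, 1–2 years,
>2 years; empty cells borrow the nearest earlier band).  AAP exposure is
stored as mean treated days per cycle in each (state, band, arm) cell, so
lifetime investigational cost is **exactly linear** in the daily price —
the property the threshold analysis exploits.

Unit costs for encounters, the flat SRE/SAE premium (£1,200), per-cycle
monitoring (£120) and medication-stop cost (£50) are documented package
defaults at plausible NHS magnitudes, fully overridable; the end-of-life
care cost is £6,897, charged once at death and to prostate-cancer deaths by
default (a switch extends it to all deaths).

## Lifetime simulation

Patient-level Markov microsimulation, continuous event times discretised
onto 42-day cycles for accrual, 45-year horizon (long enough to capture
essentially all lifetimes given the youngest patients average ~55 years).
Forty replicate lifetimes per profile in deterministic runs, 25 in PSA
iterations (500 iterations), both configurable.  Every profile is simulated
under both arms (counterfactual pairing with common random numbers per
profile), then averaged within arm × subgroup.

Other-cause mortality uses the trial-fitted model up to the splice day
(last documented follow-up, default 5 years) and a Gompertz hazard
h(age) = b·e^(a·age) beyond it, sampled conditional on survival to the
splice.  Defaults a = 0.095/yr, b = 2.6e−5/yr approximate published UK male
life-table mortality (hazard doubling every ~7.3 years, ~2%/yr at age 70);
national life tables are not redistributable in the package, so these are
the package's own calibration and both parameters are overridable.  Age
enters through band midpoints (55/65/73 for the three age groups).

QALYs are area-under-the-curve: per cycle, state utility × exact fraction
of the cycle alive × discount factor, summed.  Discounting is 3.5%/year for
costs and outcomes, applied at cycle midpoints (switchable to cycle start);
midpoint discounting reproduces the continuous annuity integral to ~0.05%.
Accrual by exact day overlap avoids half-cycle bias.  Continuous-time
event sampling (rather than per-cycle transition probabilities) was chosen
as it is equivalent in distribution with less discretisation error.

## Economic evaluation

ICER = ΔC/ΔQ with dominance labels when the signs disagree and an explicit
"undefined" at ΔQ = 0.  PSA redraws the two-part utility and cost
coefficient vectors from multivariate normals (fitted covariances;
non-PSD matrices are repaired by eigenvalue clipping with a warning) and
the unit-cost items and state/band cost cells from mean-preserving gamma
distributions (CV 0.2 by default); survival-coefficient redraw is not
performed by default.  The CEAC uses the net-monetary-benefit definition,
CEAC(λ) = P(λΔQ − ΔC > 0), which is robust to mixed ΔQ signs and verified
in tests against quadrant counting; 95% intervals are percentile-based.
Willingness-to-pay defaults are £13,000/£20,000/£30,000 per QALY.

The price-threshold analysis is closed-form: with D the discounted
incremental AAP-treated days recorded by the simulator,
ΔC(p) = ΔC(p₀) − (p₀−p)·D, so the price meeting ICER = λ is
p = p₀ − (ΔC(p₀) − λΔQ)/D and the break-even price is p₀ − ΔC(p₀)/D
(reported as undefined when negative).  Because the simulator uses common
random numbers, a re-simulation at a different price reproduces the closed
form exactly, which the tests assert.

## Synthetic data generator

The generator is the package's stand-in for confidential patient-level
trial data and defines the study conditions for all tests.  It emulates: a
1:1 two-arm randomisation of ~48% M0 / 44% bone-metastatic / 8% visceral
patients; competing-risks multistate trajectories from per-transition
exponential (or Weibull) hazards — naive-exit rates split across
destinations roughly as transition usage is observed in this population,
with a first-event log hazard ratio of −0.9 for the AAP arm and −0.2 after
castration resistance; age-dependent other-cause mortality; EQ-5D-3L
panels on the protocol visit grid (6-weekly to 6 months, 12-weekly to
2 years, 6-monthly to 5 years, laid out in whole weeks so the last visit
falls on day 1666), generated by drawing a latent utility per visit
(point mass at full health, gamma disutility otherwise, calibrated so
naive-state means sit near 0.75–0.80 and CRPC means near 0.63–0.74) and
mapping it to the nearest tariff profile; questionnaire missingness that
is missing-at-random given arm, disease phase and time by default (MCAR
switch available) so the imputation step is non-trivially exercised; and
resource-use records including treatment-policy-driven AAP exposure
(metastatic: until failure; non-metastatic: at most 2 years), a 12.6%
late-AAP fraction in the SOC arm starting at castration resistance with
the dose field always missing, a continuous ADT backbone, Poisson
encounter processes, and serious adverse events.

What it does **not** emulate: staggered recruitment and calendar-time
pathway changes (the era covariate is sampled, not mechanistic), real
covariate correlation structure, within-patient utility autocorrelation
beyond the state process, informative censoring, or dose titration.
Passing recovery tests therefore establishes that the estimation machinery
is correct under the stated generating process, not that any particular
real-world dataset satisfies those assumptions.

## Problem sizes and numerics

Test and example runs use cohorts of 150–500 patients, recovery
simulations of 2,000–10,000 observations or replicates, and reduced
imputation/PSA counts (e.g. 2–3 imputations, tens of PSA iterations);
these sizes were chosen to make the Monte-Carlo error small relative to
the 3-standard-error acceptance bands while keeping each suite quick to
run, and all are package parameters rather than fixed constants.  Times
inside the survival module are in years; event days are floats with a
0.5-day offset applied to same-day transition chains to preserve strict
ordering.  Optimisation is BFGS with a Nelder-Mead fallback; degenerate
fits (all-censored data, too few distinct event times for the requested
spline df, empty model lists) raise informative errors rather than fitting
silently.

## Known limitations

- The supplementary unit-cost and fitted-coefficient tables of the
  motivating analysis are unpublished; package unit costs are documented
  plausible defaults, so absolute cost levels in examples are
  illustrative, not reproductions.
- Within-trial utility regression ignores serial correlation beyond robust
  clustering (working independence), as is standard for GEE-based
  two-part models.
- The Gompertz splice applies one national mortality schedule to all
  profiles apart from age-band midpoints; no cohort or deprivation
  adjustment.
- The boundary of the two-part cost model is searched only if requested;
  the default £1,500 is taken as given.
- No value-of-information analysis, no multi-comparator frontier, and no
  budget-impact machinery.
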