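# cuapath

Lifetime cost-utility microsimulation for treatment pathways in newly
diagnosed advanced prostate cancer: does adding abiraterone acetate plus
prednisolone (AAP) to standard-of-care long-term androgen-deprivation
therapy (ADT) represent value for money to a health system, and at what
drug price would it?

The package is written for health economists and trial statisticians who
need a *tested, reusable* version of this class of trial-based decision
model: every stage — from patient-level data to the incremental
cost-effectiveness ratio (ICER) — is an importable, unit-tested function,
and a synthetic-data module with known ground truth makes the whole chain
verifiable by parameter recovery without access to confidential trial data.

## The model

Patients move through nine health states: three hormone-naive entry states
(HS1 non-metastatic/node-only, HS2 bone metastases, HS3 visceral
metastases), four castration-resistant (CRPC) states (HS4–HS7, with HS6 for
skeletal-related events after bone metastasis), and two absorbing death
states (HS8 prostate-cancer death, HS9 other causes).  25 transitions are
allowed: 11 among the alive states plus each alive state to each death.

- **Survival.** Parametric time-to-event models are fitted by maximum
  likelihood for nine model groups: a joint first-event model for
  failure-free survival (all exits from HS1–3, a flexible parametric spline
  with 5 degrees of freedom on the log cumulative-odds scale,
  log((1−S(t))/S(t)) = s(log t; γ) + xᵀβ, offered alongside exponential,
  Weibull, lognormal and generalised-gamma fits), a joint age-dependent
  other-cause-death model, a joint model for moves into the worst CRPC
  state, and six single transitions.  Selection is by AIC.
- **Utilities.** EQ-5D-3L responses are scored with the UK value set
  (packaged, injectable), missing scores are multiply imputed by chained
  equations with predictive mean matching (5 imputations × 30 iterations,
  by arm), and a two-part regression — logit for P(u = 1), gamma with
  identity link for the disutility 1−u — gives E[u] = p + (1−p)(1−m).
- **Costs** (English NHS perspective, 2017–18 GBP). Three categories:
  investigational medication (abiraterone £97.68/day list price +
  prednisolone), other specific expensive medications, and general disease
  management, the latter modelled in two parts around a £1,500-per-cycle
  boundary (generalised gamma below, Gaussian above).
- **Simulation.** A patient-level Markov microsimulation in continuous time,
  accrued on 42-day cycles to a 45-year horizon; other-cause mortality is
  spliced with a Gompertz life-table hazard beyond trial follow-up; QALYs
  and costs are discounted at 3.5%/year.
- **Economics.** ICER = ΔC/ΔQ per baseline subgroup (M0 vs M1);
  probabilistic sensitivity analysis (multivariate-normal coefficient
  draws, gamma cost draws, 500 × 25-simulation iterations) feeding the
  cost-effectiveness plane and acceptability curve CEAC(λ) =
  P(λΔQ − ΔC > 0); and a closed-form drug-price threshold analysis using
  the exact linearity ΔC(p) = ΔC(p₀) − (p₀−p)·D, where D is the discounted
  incremental AAP-treated days.

## Worked example

`examples/04_lifetime_simulation.py` runs the full pipeline on a 200-patient
synthetic cohort (10 simulated lifetimes per profile) and prints:

```
subgroup     arm  qalys  life_years  cost_total
      M0 AAP_SOC   7.77       13.44   110230.21
      M0     SOC   5.73        9.03    48278.68
      M1 AAP_SOC   5.39        9.17   258404.29
      M1     SOC   3.03        4.60    34141.84

subgroup  delta_cost  delta_qalys     icer
      M0    61951.53         2.04 30429.24
      M1   224262.45         2.36 94918.74
```

Reading: in the synthetic world, adding AAP gains about 2 discounted QALYs
per patient in each subgroup but carries the drug-acquisition cost for the
whole (much longer) failure-free period, so the cost per QALY gained ends
up at roughly £30k (M0) and £95k (M1) at the full list price — the ICER is
dominated by the abiraterone price, which is why the threshold analysis in
`examples/05_threshold_and_psa.py` is the decision-relevant output.  The
other examples demonstrate cohort generation, survival fitting, and the
utility/cost regressions individually.

A thin CLI wraps the same pipeline:

```bash
cua all --seed 1 --out results          # or: generate | fit | simulate | evaluate
```

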