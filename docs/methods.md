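# Methods

This note documents the models, parameters and design choices behind
`actdose`: what the controller computes, what the virtual patient
simulates, what the trial runner measures, and what the statistics
module reports.  Nothing here states an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## 1. The dosing controller

The controller holds the ACT inside a goal window `[low, high]`
(default 300–350 s, center 325 s, supratherapeutic threshold 400 s).

**Initialization.** The first bolus is
`r_d · weight · φ(ACT₀)` with per-anticoagulant rates `r_d`
(units/kg): apixaban 120, rivaroxaban 120, dabigatran 90, warfarin 75,
none 120.  The proximity factor
`φ(ACT₀) = clamp((low − ACT₀)/(low − ACT_ref), 0, 1)` needs an anchor
`ACT_ref` at which no down-scaling occurs; 120 s is used, a typical
unanticoagulated ACT.  A `phase1` preset keeps the earlier uniform
protocol (120 units/kg for any DOAC, 100 without anticoagulation;
infusions 18/15 units/kg/h) selectable for comparison.

**Units.** Infusion table entries are read as units/kg **per hour**
(27/25/18/24/24 for apixaban/rivaroxaban/dabigatran/warfarin/none).
A per-hour denominator is the only interpretation compatible with
clinical heparin infusion practice; it is an interpretation, not a
measured fact.

**Sensitivity adaptation.** The pair (bolus `B`, observed rise `ΔACT`)
gives `s_obs = ΔACT/(B/weight)`, clamped to `[s_min, s_max]` =
[0.3, 5.0] s per unit/kg.  The first observation sets `S = s_obs`;
later ones update `S ← (1−α)·S + α·s_obs` with `α = 0.5`.  Exponential
smoothing is the simplest update consistent with per-cycle refinement
toward a steady state; the clamp guarantees `S` stays in
`[s_min, s_max]` under any input sequence, including adversarial ones.
A non-positive `ΔACT` after a bolus is physiologically implausible: the
measurement is flagged suspect (the bedside rule is to redraw) and the
observation is floored at `s_min`.

**Feedback law.** With error `e = center − ACTₙ` and drift
`trend = ACTₙ − ACTₙ₋₁` (taken as 0 when a bolus intervened — a bolus
step response is not drift, and damping it would wrongly slash the
infusion on the first adjustment):

| region | bolus | infusion (units/kg/h) |
| --- | --- | --- |
| `ACTₙ < low` | `clamp(weight·e/S, 0, 6000)` units, rounded to 100 | `rate + g·e − d·trend` |
| `low ≤ ACTₙ ≤ high` | 0 | `rate + g·e − d·trend` |
| `ACTₙ > high` | 0 | pump 0 until next draw; maintenance rate remembered |

with gain `g = 0.2` (units/kg/h per second of error), damping
`d = 0.1`, and the rate clamped to [0, 40] units/kg/h.  The two hold
regions (above `high`, and above the 400 s threshold) behave
identically; holding rather than proportionally trimming was chosen
because under near-zero-order heparin elimination a high excursion
decays very slowly, and a trim leaves the ACT elevated — and exposed to
measured >400 s readings — for tens of minutes.  The maintenance
infusion starts only after the first post-bolus ACT, at the per-drug
table rate scaled by `clamp(s_ref/S, 0.5, 2)` with `s_ref = 1.5`, so a
weak bolus responder also receives a proportionally stronger infusion.

**Cadence.** ACTs are requested every 10 min (configurable 10–15)
until three consecutive values sit in goal — the steady-state
criterion — after which the interval extends to 30 min; any excursion
resets the streak.

**Determinism.** Every operation is a pure function of
(state, inputs, parameters): identical inputs give bit-identical
recommendations, which the session-replay mechanism (`replay_events`)
relies on to resume logged cases.

Covariates beyond anticoagulant, weight and baseline ACT (sex, age,
renal and liver function, platelets, hours since last dose) are
recorded on the patient profile but do not enter the v1 dose math; the
regression tooling in `actdose.stats` exists precisely to quantify
their predictive value before any such extension.

## 2. The virtual patient

Heparin level `h` (units/kg) follows one-compartment kinetics

    dh/dt = infusion(t)/weight − elimination(h)

with either first-order elimination (`k_e = ln2/half_life`; closed form
used) or Michaelis–Menten elimination `V_max·h/(K_m + h)` (RK4 at a
fixed ≤0.5 min step; the linear-mode integrator agrees with the closed
form to <1e-6 relative error, which the tests verify).  The ACT
response is `ACT = ACT₀ + s·h/(1 + h/h_sat)`, linear when
`h_sat = ∞` (the default), and the assay multiplies by lognormal noise
with mean 1 and CV `assay_cv`.

**Why saturable elimination.** Unfractionated heparin clearance is
dose-dependent.  A single first-order half-life cannot simultaneously
make a ~120 units/kg bolus raise the ACT into the goal window *and*
make a ~25–27 units/kg/h infusion sufficient to keep it there (the
required steady state `r/k_e` comes out far from the bolus-scale
level).  With `V_max = 35` units/kg/h and `K_m = 40` units/kg the two
facts coexist: the tests verify that on the zero-dispersion apixaban
patient a 120 units/kg bolus lands the first ACT in [300, 400] and the
default 27 units/kg/h infusion keeps the true ACT inside [300, 350]
over a procedure-length horizon (the property is checked over 150 min
from the post-bolus state, not asymptotically).

**Population defaults** (lognormal draws parameterised by mean and CV;
a zero CV returns the mean exactly):

| group | baseline ACT (s) | sensitivity (s per unit/kg) |
| --- | --- | --- |
| apixaban | 130 (CV 0.10) | 1.5 (CV 0.20) |
| rivaroxaban | 130 (CV 0.10) | 1.55 (CV 0.20) |
| dabigatran | 130 (CV 0.10) | 2.3 (CV 0.15) |
| warfarin | 150 (CV 0.10) | 2.4 (CV 0.15) |
| none | 120 (CV 0.08) | 1.5 (CV 0.20) |

Weight 97 kg (CV 0.22); `V_max` 35 units/kg/h (CV 0.15), `K_m` 40
units/kg shared.  The case mix defaults to apixaban 0.75, rivaroxaban
0.12, warfarin 0.11, dabigatran 0.02.  Warfarin patients run a higher
baseline and sensitivity, so the protocol's lower 75 units/kg bolus
remains adequate; dabigatran patients are the most sensitive group,
consistent with a 120 units/kg bolus routinely overshooting 400 s and
the protocol's reduction to 90 units/kg.  None of these latent values
is claimed as measured; they are chosen once to make the published
dose table self-consistent and are all configurable.

**Assay CV.** Point-of-care ACT devices are specified at ≤10% CV; that
is an upper limit, not a typical operating value.  The default is 0.05.
At 0.08–0.10 measurement noise, not dosing strategy, dominates both
arms' outcome rates (false below-goal readings trigger real boluses,
which ratchet the true ACT upward — there is no symmetric way to remove
heparin), which is neither clinically plausible nor useful for
comparing policies.

**What the generator does not emulate.** No protamine reversal, no
bleeding or complication model, no drug–drug interactions, no
inter-operator variation in when transseptal puncture actually happens,
and no correlation between sensitivity and renal/hepatic covariates.
Passing tests therefore show that the controller behaves correctly
against this model class and dominates the emulated manual policy under
these conditions — not that it would reproduce any specific clinical
cohort's numbers.

## 3. Simulated procedures and outcomes

`run_case` applies every recommendation verbatim (100% adherence),
starting with the initial bolus at t=0 after a baseline ACT draw.  The
engine arm additionally implements the suspect-value pathway: a
below-goal reading immediately following a therapeutic one, with no
intervening bolus, is flagged and confirmed by a redraw 2 min later
before any dosing; both draws are charted and both count toward
outcomes.  The emulated manual practice uses a fixed 100 units/kg
initial bolus (no per-drug or baseline adjustment), a fixed 18
units/kg/h infusion started after the first ACT, checks every 15 min,
and a 2,500-unit re-bolus delivered 7 min after any subtherapeutic
reading.  These manual defaults are an emulation of undocumented
historical practice, deliberately placed so the control arm's outcomes
are of the same order as historically reported ones; that placement is
circular by construction and is used only as a plausibility anchor,
never as validation.

Outcomes per case (all pure functions of the event record, stable
under serialization round-trips):

* **time to goal** — minutes from the initial bolus to the first
  measured ACT >300 s, censored at the procedure duration (150 min
  default) if never reached;
* **any ACT >400 s** — anywhere in the procedure;
* **any/minutes ACT <300 s in the LA** — evaluated inside the
  left-atrial window, operationalised as [time of the second post-bolus
  ACT (transseptal puncture), duration − 10 min]; the minutes metric
  carries each measurement forward to the next (step interpolation).

## 4. Statistics

* Odds ratios use the Woolf (log) interval,
  `exp(ln OR ± 1.96·√(Σ 1/cell))`, with the Haldane–Anscombe 0.5
  correction (flagged) when a cell is zero.  Woolf reproduces the
  published interval for the below-goal outcome at two decimals; the
  published interval for the >400 s outcome (0.07–0.59) differs from
  Woolf (0.08–0.59) in the lower bound, so only the first is used as an
  exact check.
* Chi-square (Pearson, no continuity correction), two-sided Fisher
  exact, and the Student (pooled) t test — Welch behind a flag — are
  delegated to scipy; the test suite cross-checks Fisher against full
  hypergeometric enumeration on every 2×2 table with margins ≤12 and
  the t statistic against the textbook formula.
* Linear and logistic fits are statsmodels OLS/Logit with Wald 95%
  intervals; exact collinearity raises an error naming the offending
  columns, perfect separation is flagged with no estimate.  Logistic
  tables carry `exp(β)` as odds ratios; on grouped 2×2 data this equals
  the closed-form OR (saturated model), which the tests verify to six
  significant digits.
* `univariate_then_multivariate` fits each candidate alone, promotes
  those with p ≤ 0.05 (two-sided throughout), applies declared
  preferences for derived twins (weight kept over BMI, since BMI is a
  function of weight), drops promoted predictors with VIF ≥ 10 worst
  first (a duplicated column has infinite VIF and always loses a copy),
  and fits the joint model.  `synthetic_bolus_dataset` provides ground
  truth for recovery checks: weight (+95 units/kg), baseline ACT (−80
  units/s) and warfarin (−2,800 units) drive the response, BMI is a
  collinear decoy, and age is pure noise.  With one pure-null candidate
  screened at α = 0.05, exact recovery of the true set is expected in
  ~95% of replicates; the candidate set was sized at design time so the
  ≥90% recovery check has that headroom.  The acceptance check runs 200
  replicates at n = 500.
* SUS scoring is standard: odd items contribute `score−1`, even items
  `5−score`, total × 2.5; range exactly [0, 100] in steps of 2.5, with
  68 (average) and 80.3 (excellent) as reference thresholds.

## 5. Numerical choices and degenerate inputs

* Boluses are rounded to 100 units (syringe practicality); `bolus_round
  = 0` disables rounding for exactness checks.  Supplemental boluses
  are clamped to [0, 6000] units, infusion rates to [0, 40] units/kg/h.
* A baseline ACT already at or above the goal floor yields a zero
  initial bolus; with nothing to calibrate against, the engine runs
  from the prior sensitivity (1.5 s per unit/kg).
* A procedure shorter than the first sampling interval produces a
  single-bolus record with censored outcomes.
* RK4 integration uses the largest step ≤0.5 min that divides each
  inter-event segment evenly; heparin level is floored at 0.
* Session logs serialise floats with `repr` so write→read round-trips
  are exact; configs are a flat `key = value` dialect in which unknown
  keys are errors.

## 6. Problem sizes

The test suite simulates 600 cases per arm for the directional trial
property and 200 replicates at n = 500 for parameter recovery; the
acceptance script uses the same sizes.  These sizes put the Monte-Carlo
standard error of each compared rate near one percentage point, small
against the effect sizes involved, while keeping a full run in tens of
seconds.

## 7. Known limitations

* The controller's functional form (proportional with smoothed inverse
  sensitivity) is an open stand-in for whatever a production system
  implements; only its externally specified behaviours are matched.
* The PK/PD model is minimal by intent; absolute simulated outcome
  rates depend on latent parameters no desk simulation can pin down,
  so only directional and structural claims are tested.
* Simulated adherence is 100%; real adherence is a descriptive metric
  of logged sessions, not something the simulator varies.
* Covariate effects (sex, renal function) exist in the synthetic
  regression data only as validation ground truth; the dose math
  deliberately ignores them pending a real derivation/validation study.
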