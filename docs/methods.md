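# Methods

`wardsim` is a stochastic, discrete-time model of a referral-hospital
maternity ward in a resource-constrained setting.  Its purpose is to
connect resource decisions — how much medicine is on the shelf, how many
nurses and doctors are on each shift, how many patients arrive — to
maternal mortality, at the level of individual patients and individual
15-minute treatment decisions.

## The model

Time advances in cycles of 15 minutes (96 per day).  Every cycle runs
four steps in fixed order.

**1. Admission.**  At most one patient arrives per cycle, as a Bernoulli
draw with the current shift's admission probability.  With probability
equal to the configured complication incidences, the patient carries one
of five potentially life-threatening complications — postpartum
hemorrhage, preeclampsia, eclampsia, uterine rupture, sepsis — otherwise
she is an uncomplicated delivery.  Each complication's initial severity
is a draw from a truncated normal on (0, 1), interpreted as the
*probability of mortality* p: the chance of dying over the whole
remaining hospital stay.  The distribution's mean is the complication's
case fatality rate; its standard deviation is pinned by requiring the
severe-maternal-outcome (SMO) mortality to sit two standard deviations
above the mean, so that 2.5% of arrivals are at SMO-level severity:
sd = (p_SMO − μ)/2.  Sampling is by inverse CDF on the truncated
quantile range (exact and reproducible; no rejection loop).

**2. Allocation.**  Each complication maps to an entry *treatment plan*:
a bundle of drug doses (in pack fractions) and nurse/doctor visits, each
with a visit frequency, plus a duration in treated cycles, an efficacy
η, and an optional successor plan (plans chain, e.g. active treatment →
recovery → discharge).  Patients are triaged in strictly descending
composite mortality

    p_c = 1 − ∏_k (1 − p_k)

(the independent-hazards combination across the patient's conditions;
ties broken by earlier admission, then patient id).  A patient is
treated this cycle only if **every** resource her plan demands this
cycle — each drug dose and each staff unit — is available; if a single
one is missing, nothing is taken and she goes untreated.  Staff flagged
`consecutive_hold` stay reserved with the patient between visits until
the plan completes or the patient dies; all other staff return to the
pool at the end of the cycle.

**3. Evaluation.**  Treated conditions improve geometrically:
p → p(1−η) per cycle, so after c treated cycles p(c) = p₀ rᶜ with
r = 1 − η.  Untreated conditions worsen: with deterioration rate λ and
consecutive-untreated counter c (reset to 0 by any treated cycle),

    p → p^(λ/(λ+c)),

whose c-fold composition is the closed form
p(c) = p₀ ^ (λᶜ Γ(λ+1) / Γ(λ+c+1)) — a sigmoidal climb toward (never
reaching) 1; larger λ means slower deterioration.  The exponent is
computed via log-gamma differences, so large c or λ cannot overflow.
Survival is then drawn per patient: since p_c covers the whole remaining
stay of n cycles, the per-cycle draw uses the scaled probability p
solving (1 − p)ⁿ = 1 − p_c, with n the treated-cycles remaining in the
patient's plan chain (floor 1).  A uniform variate at or below p kills
the patient; her held staff return to the pool immediately.

**4. Restock & advance.**  Inventory gains its restock amounts at every
multiple of the restock interval (default monthly = 30 days = 2880
cycles; cycle numbering for the schedule is 1-based, so a 90-day run
restocks at cycles 2880, 5760, 8640).  The shift clock then advances;
staffing totals and the admission probability switch at shift
boundaries.  Held staff carry across boundaries; pool availability is
recomputed as max(on-shift total − held, 0), so availability + held
always accounts for the full on-shift presence.

### Interpretive choices the update rules force

* Plan *duration* counts **treated** cycles: untreated cycles advance
  the untreated counter instead of plan progress, so scarcity implicitly
  extends stays (and therefore congestion — a feedback loop that is one
  of the model's central mechanisms).
* Deaths are attributed to the patient's condition with the largest
  individual p at the time of death (needed for per-complication case
  fatality rates; the composite draw itself has no single cause).
* The untreated counter starts at 1 on the first untreated cycle and the
  per-cycle exponent uses the current counter value; this is the unique
  reading under which the per-cycle update composes exactly to the
  Γ-function closed form.
* Probabilities live on [0, 1): exactly 0 is reserved for the
  uncomplicated baseline (such patients cannot die), exactly 1 is never
  attained — deterioration is capped at the largest double below 1.
* Patients admitted in a cycle are evaluated for survival in that same
  cycle; a plan's demands at progress points between visits may be
  empty, and meeting an empty demand still counts as a treated cycle.

## Randomness and pairing

Each trial derives two RNG streams from one seed: an *arrival* stream
(admission draws, complication assignment, severities) and a *survival*
stream.  Arrival-stream consumption never depends on resource state, so
two configurations run with the same seed see the identical patient
sequence — common random numbers — and differ only through what the ward
could do for those patients.  Scenario sweeps reuse seeds across cells
(trial i of every cell uses base_seed + i) to sharpen paired contrasts.
Replicate trials use consecutive seeds.  Everything is bit-reproducible
from (config, seed).

Note that strict path-wise dominance (more resources ⇒ never more deaths
*per seed*) is not a theorem of this model: because allocation is
all-or-nothing across two resource classes, an extra nurse can divert a
drug dose from a lower-priority patient.  Dominance holds in aggregate
and is tested that way, over paired trials with large resource
contrasts.

## Calibration

Three parameter groups are set in sequence:

1. **Severity SDs** — analytic, from the SMO two-standard-deviations
   rule.
2. **Treatment efficacies** — analytic: η is chosen so that under
   complete, timely treatment the *mean* case of each complication
   decays to a mortality floor of 10⁻¹⁰ exactly at the end of its plan
   chain: η = 1 − (10⁻¹⁰/μ)^(1/D), D the chain's total treated cycles.
   The decay constant r is stored alongside η: for η near 1,
   reconstituting r as 1 − η loses up to seven significant digits to
   cancellation, and with the stored r the floor is hit to ~D·ε relative
   (≈10⁻¹⁴ for D ≈ 200), which is the double-precision limit.
   Every plan in a complication's chain carries that complication's η;
   the packaged configuration keeps chains disjoint per complication so
   the assignment is unambiguous.
3. **Deterioration rates** — simulation-based.  The simulated case
   fatality rate is monotonically decreasing in λ (slower deterioration,
   fewer deaths), so each complication's λ is fitted by bisection on
   log₁₀ λ over [10⁻², 10⁴] against its target CFR.  Every objective
   evaluation reuses the same trial seeds, making the noisy objective a
   *fixed* monotone step function of λ; the search is therefore
   deterministic and idempotent.  Complications are fitted sequentially,
   each with the others held at their latest rates.  Targets outside the
   bracket's achievable CFR range (including a target of exactly 0,
   which positive severity means make unreachable) are flagged as
   non-converged with the closer endpoint reported.

Incidence rates are not fitted — they are the admission mixture, an
input — and the calibration report verifies this decoupling by showing
incidence unchanged across deterioration settings.

## The packaged baseline configuration

The default configuration emulates the Mnazi Mmoja Hospital maternity
ward.  Observed quantities:

| input | value |
|---|---|
| shifts (8 h each) | morning 5 nurses/3 doctors, evening 3/2, night 3/1 |
| admission probability per 15 min | 0.4 / 0.28 / 0.625 |
| complicated fraction of admissions | 13.05% (343 of 2628 records) |
| oxytocin | 200 packs (~20,000 IU), monthly restock |
| hydralazine | 11 packs (~2,200 mg/mL), monthly restock |
| horizon | 90 days (8640 cycles), 50 replicate trials |

Shift boundary times are not observed; symmetric 8-hour shifts starting
at 06:00 are the default and are configurable.  Under them the expected
admission load is 32·(0.4+0.28+0.625) ≈ 41.8 patients/day ≈ 1253 per
30-day month.

Severity means (CFR-scale, per complication), the SMO mortality (0.20),
deterioration rates, and all plan dosages/frequencies/durations are
**illustrative**: the clinical values they stand in for come from
unpublished ward records and a separate clinical study.  They are marked
`"illustrative": true` in the config and were chosen once, for realism:
stays range from 16 h (uncomplicated delivery: active delivery with a
prophylactic oxytocin dose, then postnatal observation) to 3 days
(eclampsia, uterine rupture, sepsis); every delivery consumes oxytocin;
hydralazine is demanded only by the hypertensive-disorder plans; uterine
rupture opens with a surgery plan that holds two nurses and a doctor
continuously for three hours.  Nurse visit frequencies are sized so the
ward runs near its staffing capacity, with shortages concentrated on the
night shift (three nurses, one doctor, but the *highest* admission
probability) — the regime in which resource questions are interesting.

## What the synthetic generator does and does not emulate

The generator reproduces the *structure* of the setting: shift-varying
arrivals and staffing, a complication mixture, severity heterogeneity
with an SMO tail, plan chains with resource footprints, and inventory
dynamics.  It does not emulate: multiple simultaneous complications
(supported by the composite math and a config flag, but off by default,
matching the single-complication scope of the source records),
complications acquired mid-stay, diagnostic error, age or obstetric
history, ICU/blood/surgical-theatre logistics, or patient-procured
medication.  Passing tests therefore demonstrate the mechanism —
triage, scarcity, deterioration, supply cycles — not a validated
forecast for any real ward; quantitative claims about a real ward
require calibrating severity means, SMO mortality and plan parameters to
that ward's records.

## Numerical and testing notes

* Closed forms are exercised against their iterated updates to 1e-10
  relative over randomized parameters (treatment, and deterioration via
  log-gamma exponents, c up to 200).
* The scaled-mortality identity is checked by Monte-Carlo: 10⁵
  replicates of n per-cycle draws reproduce the stay-level probability
  within 3 binomial standard errors.
* Staff conservation is asserted every cycle of full 90-day runs
  (available + held = on-shift total; the pool never overdrawn), and the
  drug ledger (final = initial + restocks − dispensed) balances to
  1e-9 packs absolute — the residual is float addition order, nothing
  is lost or created.
* Greedy triage is compared against an independent brute-force
  sickest-first feasibility oracle on cohorts of up to six patients over
  randomized plans, stocks and staffing.
* Calibration is validated by parameter recovery: simulate at a known λ,
  take the achieved CFR as the target, refit from a wrong starting
  point, and require convergence back to that CFR.  λ itself is
  identified only up to the local flatness of the CFR curve.
* Test and example problem sizes are scaled down (days-to-weeks
  horizons, single-digit trial counts) from the 90-day × 50-trial
  production setting; the dynamics are identical, only Monte-Carlo
  resolution differs.  Extreme-stockout cells run slower than baseline
  cells because untreated patients accumulate (census grows), which is
  the congestion feedback operating as designed.

## Known limitations

* Deaths are attributed to the single worst condition; with
  multi-morbidity enabled, per-complication CFRs are conservative for
  the less-severe conditions.
* Staff are fungible whole units with no skill mix, fatigue, or
  handover costs; a held unit crossing into a smaller shift can
  transiently exceed the scheduled total (availability floors at zero).
* The admission process is at most one patient per cycle; bursts beyond
  one per 15 minutes are not representable except through the
  probability ceiling of 1.
* Restocking is deterministic and punctual; real supply chains are
  neither, and the sweep machinery (restock on/off, initial stock
  levels) is the intended way to explore that gap.
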