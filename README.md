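# wardsim

Stochastic, discrete-time simulation of resource-dependent maternal
mortality in a referral-hospital maternity ward.

Close to 830 women die every day of preventable maternal complications,
most of them in facilities that lack the staff or medicines to treat
complications in time.  `wardsim` is a tool for hospital administrators,
health-system modelers and researchers who want to ask, quantitatively:
*if this ward had one more nurse on the night shift, or a reliable
monthly oxytocin shipment, how many maternal deaths would that avert?*
It models a maternity ward patient by patient, in 15-minute cycles,
tracking each patient's probability of mortality as treatment and
scarcity push it down and up, and each shift's staff and each drug's
stock as triage consumes them.

## The model in brief

Each 15-minute cycle runs four steps:

1. **Admission** — at most one arrival, Bernoulli with the current
   shift's admission probability; complications (postpartum hemorrhage,
   preeclampsia, eclampsia, uterine rupture, sepsis) are assigned by
   incidence, with severity p ~ truncated normal on (0, 1) whose mean is
   the complication's case fatality rate and whose upper 2.5% tail is
   pinned at the severe-maternal-outcome mortality.
2. **Allocation** — sickest first, by composite mortality
   p_c = 1 − ∏(1 − p_k); a patient is treated only if *every* drug dose
   and staff unit her treatment plan demands this cycle is available.
3. **Evaluation** — treated conditions decay geometrically,
   p → p(1 − η); untreated conditions deteriorate,
   p → p^(λ/(λ+c)) with closed form p₀^(λᶜ Γ(λ+1)/Γ(λ+c+1)); survival
   is drawn from the per-cycle probability p solving (1 − p)ⁿ = 1 − p_c
   over the n remaining cycles of stay.
4. **Restock** — inventory shipments on a schedule (default monthly),
   shift changes, clock advance.

Treatment efficacies are calibrated analytically (η such that the mean
case is cured, p = 10⁻¹⁰, exactly at the end of its plan chain);
deterioration rates are calibrated by monotone bisection of the
simulated case fatality rate against targets, with common random
numbers.  See `docs/methods.md` for the full model description and the
design choices.

## A worked example

```bash
python examples/run_baseline.py
```

runs the packaged baseline ward (observed shift staffing and admission
rates, monthly-restocked inventory, illustrative clinical parameters)
for one simulated month, five trials:

```
trials:               5 x 30 days
admissions per month: 1251
mean daily census:    37.5 (sd 7.1)
maternal deaths:      7.2 per month (sd 3.7)
mortality rate among complicated patients: 4.24%
case fatality rates (%):
  eclampsia              CFR 13.33   incidence  1.44
  postpartum_hemorrhage  CFR  0.66   incidence  4.84
  preeclampsia           CFR  7.83   incidence  4.49
  sepsis                 CFR  0.00   incidence  1.77
  uterine_rupture        CFR  0.00   incidence  1.04
```

About 1250 patients arrive per month and around 38 are in the ward at
any moment; 13% carry a life-threatening complication, and their
per-complication case fatality rates reflect how often the ward's three
night-shift nurses and its hydralazine stock fall short of the demand
in front of them.  The other examples each demonstrate one capability:

- `examples/probability_dynamics.py` — the treatment-decay and
  deterioration closed forms, cycle by cycle.
- `examples/calibrate_deterioration.py` — fitting a deterioration rate
  to a target case fatality rate by bisection with common random
  numbers.
- `examples/sweep_medicine_stocks.py` — the supply-policy question:
  oxytocin stock levels × restocking on/off, paired seeds across cells
  (in a six-week demo, mean deaths fall from 127 with an unreplenished
  50-pack stock to 35 with 200 packs restocked monthly).

## Library and command line

The primary interface is the Python API:

```python
from wardsim import default_mmh_config, run_trials, summarize, SweepSpec
from wardsim import sweep_staffing

config = default_mmh_config()           # 90 days, 50 trials
stats = summarize(run_trials(config))
print(stats.deaths_mean, stats.mortality_rate_complicated_pct)
```

A thin CLI wraps the same functions for shell use:

```bash
wardsim validate ward.json
wardsim run ward.json --months 3 --trials 50 --seed 42 --out results.json
wardsim calibrate ward.json targets.json --out calibrated.json
wardsim sweep ward.json --kind staffing --out grid.csv
```

Configurations and results are JSON (strict schema, field-path error
messages, canonical sorted-key serialization); sweep tables export as
tidy CSV, one row per cell per trial.

## Caveats

The packaged severity means, SMO mortality, deterioration rates and
treatment-plan dosages are *illustrative* stand-ins (marked
`"illustrative": true` in the config) for clinical values that come from
unpublished ward records; conclusions about a real ward require
calibrating those inputs to that ward's data.  See the limitations
section of `docs/methods.md`.
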