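"""Synthetic ward configurations.

The default configuration emulates the Mnazi Mmoja Hospital maternity
ward: three shifts with the observed staffing and admission
probabilities, five potentially life-threatening complications
(postpartum hemorrhage, preeclampsia, eclampsia, uterine rupture,
sepsis) plus uncomplicated delivery, treatment-plan chains with
prophylactic oxytocin for every delivery and hydralazine on the
hypertensive-disorder plans, and a monthly-restocked inventory.

Severity means, SMO mortality and plan dosages are *illustrative*
(flagged ``"illustrative": true`` in the config): the clinical values
they stand in for come from unpublished ward records and a separate
clinical study, so the numbers here are representative magnitudes, not
measurements.

``random_config`` produces schema-valid configurations spanning
degenerate corners (zero staff, zero stock, extreme efficacies) for
property-based testing; ``toy_cohort`` builds hand-specified
mini-cohorts for allocation and survival unit tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io_config import (
    Complication,
    DrugDemand,
    DrugStock,
    Shift,
    SimulationConfig,
    StaffDemand,
    TreatmentPlan,
)
from .model_core import calibrate_efficacy
from .ward_engine import Patient, WardState

__all__ = ["FixtureSpec", "default_mmh_config", "random_config", "toy_cohort", "toy_config"]

#: fraction of admissions with a potentially life-threatening complication,
#: from the digitized cohort: 343 complicated / (343 + 2285) total = 13.05%
COMPLICATED_FRACTION_PCT = 100.0 * 343 / (343 + 2285)


def default_mmh_config(
    horizon_days: int = 90, n_trials: int = 50, base_seed: int = 0
) -> SimulationConfig:
    """Baseline ward configuration emulating the MMH maternity ward.

    Staffing and per-15-minute admission probabilities follow the
    observed shift pattern (morning 5 nurses / 3 doctors / 0.4, evening
    3/2/0.28, night 3/1/0.625, symmetric 8-hour shifts).  Inventory
    anchors: 200 packs of oxytocin (~20,000 IU) and 11 packs of
    hydralazine (~2,200 mg/mL), restocked monthly.  Treatment
    efficacies are set analytically so the mean case of each
    complication is cured (mortality 1e-10) exactly at the end of its
    plan chain.
    """
    shifts = [
        Shift(name="morning", start_cycle=24, duration=32, nurses=5, doctors=3,
              admission_probability=0.4),
        Shift(name="evening", start_cycle=56, duration=32, nurses=3, doctors=2,
              admission_probability=0.28),
        Shift(name="night", start_cycle=88, duration=32, nurses=3, doctors=1,
              admission_probability=0.625),
    ]

    # (name, incidence %, severity mean, deterioration rate, entry plan)
    # severity means are illustrative CFR-scale values; incidences split the
    # 13.05% complicated fraction with postpartum hemorrhage most common
    comp_rows = [
        ("postpartum_hemorrhage", 5.0, 0.025, 30.0, "pph_treatment"),
        ("preeclampsia", 4.0, 0.010, 60.0, "preeclampsia_treatment"),
        ("eclampsia", 1.5, 0.060, 25.0, "eclampsia_treatment"),
        ("sepsis", 1.5, 0.050, 80.0, "sepsis_treatment"),
        ("uterine_rupture", 1.05, 0.080, 20.0, "rupture_surgery"),
    ]
    smo_mortality = 0.20  # illustrative death rate among severe maternal outcomes

    plans = [
        # uncomplicated delivery: prophylactic oxytocin at delivery, then
        # postnatal observation; 64 cycles (16 h) in total
        TreatmentPlan(
            id="normal_delivery", duration=8,
            drugs={"oxytocin": DrugDemand(dose=0.1, frequency=8)},
            nurses=StaffDemand(count=1, frequency=8),
            efficacy=0.5, successor="postnatal_observation",
        ),
        TreatmentPlan(
            id="postnatal_observation", duration=56,
            nurses=StaffDemand(count=1, frequency=28),
            efficacy=0.5,
        ),
        # postpartum hemorrhage: intensive oxytocin + nursing, 2-day stay
        TreatmentPlan(
            id="pph_treatment", duration=24,
            drugs={"oxytocin": DrugDemand(dose=0.2, frequency=8)},
            nurses=StaffDemand(count=1, frequency=2),
            doctors=StaffDemand(count=1, frequency=8),
            efficacy=0.1, successor="pph_recovery",
        ),
        TreatmentPlan(
            id="pph_recovery", duration=168,
            drugs={"oxytocin": DrugDemand(dose=0.1, frequency=48)},
            nurses=StaffDemand(count=1, frequency=16),
            efficacy=0.1,
        ),
        # preeclampsia: antihypertensive cover, 2-day stay
        TreatmentPlan(
            id="preeclampsia_treatment", duration=96,
            drugs={"hydralazine": DrugDemand(dose=0.05, frequency=48)},
            nurses=StaffDemand(count=1, frequency=8),
            doctors=StaffDemand(count=1, frequency=24),
            efficacy=0.1, successor="preeclampsia_recovery",
        ),
        TreatmentPlan(
            id="preeclampsia_recovery", duration=96,
            nurses=StaffDemand(count=1, frequency=16),
            efficacy=0.1,
        ),
        # eclampsia: hydralazine + magnesium sulfate, close nursing, 3-day stay
        TreatmentPlan(
            id="eclampsia_treatment", duration=48,
            drugs={
                "hydralazine": DrugDemand(dose=0.05, frequency=12),
                "magnesium_sulfate": DrugDemand(dose=0.1, frequency=16),
            },
            nurses=StaffDemand(count=1, frequency=2),
            doctors=StaffDemand(count=1, frequency=12),
            efficacy=0.1, successor="eclampsia_recovery",
        ),
        TreatmentPlan(
            id="eclampsia_recovery", duration=240,
            drugs={"hydralazine": DrugDemand(dose=0.05, frequency=96)},
            nurses=StaffDemand(count=1, frequency=16),
            doctors=StaffDemand(count=1, frequency=48),
            efficacy=0.1,
        ),
        # uterine rupture: emergency surgery holding theatre staff, then recovery
        TreatmentPlan(
            id="rupture_surgery", duration=12,
            drugs={"oxytocin": DrugDemand(dose=0.2, frequency=12)},
            nurses=StaffDemand(count=2, frequency=1, consecutive_hold=True),
            doctors=StaffDemand(count=1, frequency=1, consecutive_hold=True),
            efficacy=0.1, successor="rupture_recovery",
        ),
        TreatmentPlan(
            id="rupture_recovery", duration=276,
            drugs={"antibiotics": DrugDemand(dose=0.1, frequency=24)},
            nurses=StaffDemand(count=1, frequency=16),
            doctors=StaffDemand(count=1, frequency=48),
            efficacy=0.1,
        ),
        # sepsis: antibiotic course, 3-day stay
        TreatmentPlan(
            id="sepsis_treatment", duration=96,
            drugs={"antibiotics": DrugDemand(dose=0.2, frequency=24)},
            nurses=StaffDemand(count=1, frequency=8),
            doctors=StaffDemand(count=1, frequency=24),
            efficacy=0.1, successor="sepsis_recovery",
        ),
        TreatmentPlan(
            id="sepsis_recovery", duration=192,
            drugs={"antibiotics": DrugDemand(dose=0.1, frequency=24)},
            nurses=StaffDemand(count=1, frequency=16),
            efficacy=0.1,
        ),
    ]

    inventory = {
        "oxytocin": DrugStock(initial=200.0, restock_amount=200.0, restock=True),
        "hydralazine": DrugStock(initial=11.0, restock_amount=11.0, restock=True),
        "magnesium_sulfate": DrugStock(initial=500.0, restock_amount=500.0, restock=True),
        "antibiotics": DrugStock(initial=500.0, restock_amount=500.0, restock=True),
    }

    complications = [
        Complication(
            name=name, incidence_pct=inc, severity_mean=mean,
            smo_mortality=smo_mortality, deterioration_rate=lam,
            entry_plan=entry, illustrative=True,
        )
        for name, inc, mean, lam, entry in comp_rows
    ]

    cfg = SimulationConfig(
        schedule=shifts,
        complications=complications,
        uncomplicated_pct=100.0 - sum(c.incidence_pct for c in complications),
        uncomplicated_plan="normal_delivery",
        plans=plans,
        inventory=inventory,
        horizon_cycles=horizon_days * 96,
        n_trials=n_trials,
        base_seed=base_seed,
    )
    return apply_efficacy_rule(cfg)


def apply_efficacy_rule(config: SimulationConfig) -> SimulationConfig:
    """Set each complication chain's efficacy from the cure-on-time rule.

    For every complication, eta solves geometric decay of the severity
    mean to 1e-10 over the entry chain's total duration; the same eta is
    written to every plan in that chain.
    """
    chain_eta: dict[str, float] = {}
    for comp in config.complications:
        eta = calibrate_efficacy(
            comp.severity_mean, config.chain_cycles(comp.entry_plan)
        ).efficacy
        cur = comp.entry_plan
        while cur is not None:
            chain_eta[cur] = eta
            cur = config.plan(cur).successor
    for plan in config.plans:
        if plan.id in chain_eta:
            plan.efficacy = chain_eta[plan.id]
    return config


@dataclass(frozen=True)
class FixtureSpec:
    """Knobs for randomized configuration generation."""

    seed: int = 0
    max_complications: int = 4
    max_chain_depth: int = 3
    richness: str = "baseline"  # "scarce" | "baseline" | "abundant"


def random_config(spec: FixtureSpec) -> SimulationConfig:
    """Generate a schema-valid random configuration (pure function of seed).

    Draws span degenerate corners — zero staff, zero stock, single
    complication, efficacies of 0 and 1 — so property tests exercise the
    engine well outside the comfortable baseline regime.
    """
    rng = np.random.default_rng(spec.seed)
    richness = {"scarce": 0.15, "baseline": 1.0, "abundant": 5.0}[spec.richness]

    drugs = ["drug_a", "drug_b"]
    n_comp = int(rng.integers(1, spec.max_complications + 1))

    plans: list[TreatmentPlan] = []

    def make_chain(prefix: str) -> str:
        depth = int(rng.integers(1, spec.max_chain_depth + 1))
        ids = [f"{prefix}_{k}" for k in range(depth)]
        for k, pid in enumerate(ids):
            eta = float(rng.choice([0.0, 1.0, rng.uniform(0.01, 0.5)]))
            plan_drugs = {}
            for d in drugs:
                if rng.random() < 0.5:
                    plan_drugs[d] = DrugDemand(
                        dose=round(float(rng.uniform(0.05, 0.5)), 3),
                        frequency=int(rng.integers(1, 17)),
                    )
            plans.append(
                TreatmentPlan(
                    id=pid,
                    duration=int(rng.integers(1, 49)),
                    drugs=plan_drugs,
                    nurses=StaffDemand(
                        count=int(rng.integers(0, 3)),
                        frequency=int(rng.integers(1, 9)),
                        consecutive_hold=bool(rng.random() < 0.3),
                    ),
                    doctors=StaffDemand(
                        count=int(rng.integers(0, 2)),
                        frequency=int(rng.integers(1, 9)),
                    ),
                    efficacy=eta,
                    successor=ids[k + 1] if k + 1 < depth else None,
                )
            )
        return ids[0]

    uncomplicated_entry = make_chain("delivery")
    complications = []
    remaining = 40.0
    for i in range(n_comp):
        inc = round(float(rng.uniform(0.5, remaining / (n_comp - i))), 3)
        remaining -= inc
        mean = float(rng.uniform(0.005, 0.15))
        complications.append(
            Complication(
                name=f"comp_{i}",
                incidence_pct=inc,
                severity_mean=mean,
                smo_mortality=mean + float(rng.uniform(0.05, 0.3)),
                deterioration_rate=float(10 ** rng.uniform(-1, 3)),
                entry_plan=make_chain(f"comp_{i}_plan"),
                illustrative=True,
            )
        )

    shifts = []
    starts = [0, 32, 64]
    for name, start in zip(["a", "b", "c"], starts):
        shifts.append(
            Shift(
                name=name, start_cycle=start, duration=32,
                nurses=int(rng.integers(0, 6)),
                doctors=int(rng.integers(0, 4)),
                admission_probability=round(float(rng.uniform(0.0, 0.7)), 3),
            )
        )

    inventory = {
        d: DrugStock(
            initial=round(float(rng.uniform(0, 50) * richness), 2),
            restock_amount=round(float(rng.uniform(0, 50) * richness), 2),
            restock=bool(rng.random() < 0.7),
        )
        for d in drugs
    }

    return SimulationConfig(
        schedule=shifts,
        complications=complications,
        uncomplicated_pct=100.0 - sum(c.incidence_pct for c in complications),
        uncomplicated_plan=uncomplicated_entry,
        plans=plans,
        inventory=inventory,
        restock_interval=int(rng.integers(96, 2881)),
        horizon_cycles=int(rng.integers(96, 8641)),
        n_trials=5,
        base_seed=int(rng.integers(0, 2**31 - 1)),
    )


def toy_config(
    nurses: int = 1,
    doctors: int = 1,
    stock: dict[str, float] | None = None,
    plan: TreatmentPlan | None = None,
    deterioration_rate: float = 50.0,
    severity_mean: float = 0.1,
    admission_probability: float = 0.0,
    horizon_cycles: int = 96,
    extra_plans: list[TreatmentPlan] | None = None,
) -> SimulationConfig:
    """Minimal single-shift, single-complication config for unit tests."""
    if plan is None:
        plan = TreatmentPlan(
            id="plan",
            duration=8,
            drugs={"drug": DrugDemand(dose=1.0, frequency=1)},
            nurses=StaffDemand(count=1, frequency=1),
            doctors=StaffDemand(count=1, frequency=1),
            efficacy=0.5,
        )
    stock = {"drug": 1000.0} if stock is None else stock
    return SimulationConfig(
        schedule=[
            Shift(name="all_day", start_cycle=0, duration=96, nurses=nurses,
                  doctors=doctors, admission_probability=admission_probability)
        ],
        complications=[
            Complication(
                name="c0", incidence_pct=50.0, severity_mean=severity_mean,
                smo_mortality=min(severity_mean + 0.2, 0.9),
                deterioration_rate=deterioration_rate, entry_plan=plan.id,
                illustrative=True,
            )
        ],
        uncomplicated_pct=50.0,
        uncomplicated_plan=plan.id,
        plans=[plan, *(extra_plans or [])],
        inventory={d: DrugStock(initial=q, restock=False) for d, q in stock.items()},
        horizon_cycles=horizon_cycles,
        n_trials=1,
    )


def toy_cohort(
    severities: list[float],
    config: SimulationConfig | None = None,
    **config_kwargs,
) -> WardState:
    """Hand-specified mini-cohort with no admission randomness.

    Each severity becomes one patient with the single complication at
    that mortality probability (0 means an uncomplicated patient).
    """
    cfg = config if config is not None else toy_config(**config_kwargs)
    state = WardState(config=cfg)
    comp = cfg.complications[0].name
    entry = cfg.complications[0].entry_plan
    for i, sev in enumerate(severities):
        conditions = {} if sev == 0.0 else {comp: float(sev)}
        pid = entry if sev == 0.0 else cfg.complications[0].entry_plan
        pat = Patient(i, admission_cycle=0, conditions=conditions, plan_id=pid)
        state.patients.append(pat)
        state.next_patient_id = i + 1
        state.admissions += 1
        state.cases[comp if conditions else "uncomplicated"] += 1
    return state
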