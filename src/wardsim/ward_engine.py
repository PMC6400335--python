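"""Discrete-time simulation loop of the maternity ward.

Time advances in 15-minute cycles (96 per day).  Each cycle runs four
steps in fixed order:

1. **Admission** — at most one patient arrives, with the current shift's
   admission probability; complications and severities are drawn from the
   configured incidence mix and truncated-normal severity distributions.
2. **Allocation** — treatment plans are (re)assigned, then staff and
   medicines are allocated greedily in descending order of composite
   mortality (sickest first).  A patient is treated only if *every*
   resource her plan demands this cycle is available.
3. **Evaluation** — treated conditions improve geometrically with the
   plan's efficacy; untreated conditions worsen with their deterioration
   rate; survival is then drawn against the per-cycle scaled mortality.
4. **Restock & advance** — inventory is replenished on the restocking
   schedule, transient staff return to the pool, the shift clock advances.

The engine is deterministic given (config, seed): one ``SeedSequence``
per trial is split into an *arrival* stream (admissions, complication
assignment, severities) and a *survival* stream.  The arrival stream's
consumption does not depend on resource levels, so paired scenario runs
with common seeds see identical patient sequences.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .io_config import CYCLES_PER_DAY, SimulationConfig, TreatmentPlan
from .model_core import (
    DeteriorationParams,
    EfficacyParams,
    SeverityDistribution,
    apply_deterioration_cycle,
    apply_treatment_cycle,
    composite_mortality,
    sample_severity,
    scaled_cycle_mortality,
)

__all__ = [
    "Patient",
    "WardState",
    "TrialResult",
    "step_admission",
    "assign_plans",
    "allocate_resources",
    "apply_dynamics",
    "evaluate_survival",
    "restock_and_advance",
    "run_trial",
    "run_trials",
    "make_rng_streams",
]

UNCOMPLICATED = "uncomplicated"


class Patient:
    """One admitted patient and her per-condition mortality state."""

    __slots__ = (
        "id",
        "admission_cycle",
        "conditions",
        "untreated_counter",
        "plan_id",
        "progress",
        "held_nurses",
        "held_doctors",
        "alive",
    )

    def __init__(
        self,
        id: int,
        admission_cycle: int,
        conditions: dict[str, float],
        plan_id: str,
    ) -> None:
        self.id = id
        self.admission_cycle = admission_cycle
        self.conditions = conditions  # complication name -> mortality probability
        self.untreated_counter = 0
        self.plan_id = plan_id
        self.progress = 0  # treated cycles completed in the active plan
        self.held_nurses = 0
        self.held_doctors = 0
        self.alive = True

    def composite(self) -> float:
        ps = self.conditions.values()
        if not ps:
            return 0.0
        return composite_mortality(list(ps))


@dataclass
class WardState:
    """Mutable simulation state for one trial."""

    config: SimulationConfig
    cycle: int = 0  # 0-based index of the cycle being executed
    patients: list[Patient] = field(default_factory=list)
    inventory: dict[str, float] = field(default_factory=dict)
    next_patient_id: int = 0
    # tallies
    admissions: int = 0
    discharges: int = 0
    deaths: int = 0
    cases: dict[str, int] = field(default_factory=dict)
    deaths_by_complication: dict[str, int] = field(default_factory=dict)
    dispensed: dict[str, float] = field(default_factory=dict)
    restocked: dict[str, float] = field(default_factory=dict)
    shortage_refusals: int = 0  # patient-cycles refused for lack of a drug
    staff_refusals: int = 0  # patient-cycles refused for lack of staff
    untreated_patient_cycles: int = 0
    last_allocation: dict = field(default_factory=dict)  # per-cycle staff audit
    # bookkeeping caches (built from config once)
    _plans: dict[str, TreatmentPlan] = field(default_factory=dict)
    _chain: dict[str, int] = field(default_factory=dict)
    _severity: dict[str, SeverityDistribution] = field(default_factory=dict)
    _det: dict[str, float] = field(default_factory=dict)
    _eff: dict[str, EfficacyParams] = field(default_factory=dict)
    event_log: list[tuple] = field(default_factory=list)

    def __post_init__(self) -> None:
        cfg = self.config
        self._plans = {p.id: p for p in cfg.plans}
        self._chain = {p.id: cfg.chain_cycles(p.id) for p in cfg.plans}
        self._eff = {p.id: EfficacyParams(efficacy=p.efficacy) for p in cfg.plans}
        for c in cfg.complications:
            sd = c.severity_sd
            if sd is None:
                sd = (c.smo_mortality - c.severity_mean) / 2.0
            self._severity[c.name] = SeverityDistribution(
                mean=c.severity_mean, sd=sd, smo_mortality=c.smo_mortality
            )
            self._det[c.name] = c.deterioration_rate
        if not self.inventory:
            self.inventory = {d: s.initial for d, s in cfg.inventory.items()}
        self.dispensed = {d: 0.0 for d in cfg.inventory}
        self.restocked = {d: 0.0 for d in cfg.inventory}
        self.cases.setdefault(UNCOMPLICATED, 0)
        for c in cfg.complications:
            self.cases.setdefault(c.name, 0)
            self.deaths_by_complication.setdefault(c.name, 0)

    # -- derived quantities ----------------------------------------------

    def shift(self):
        return self.config.shift_at(self.cycle)

    def held_totals(self) -> tuple[int, int]:
        n = sum(p.held_nurses for p in self.patients)
        d = sum(p.held_doctors for p in self.patients)
        return n, d

    def remaining_stay(self, pat: Patient) -> int:
        return max(self._chain[pat.plan_id] - pat.progress, 1)


@dataclass
class TrialResult:
    """Trajectories and end-of-run tallies for one seeded trial."""

    seed: int
    horizon_cycles: int
    admissions: int
    discharges: int
    deaths: int
    cases: dict[str, int]
    deaths_by_complication: dict[str, int]
    final_census: int
    census: np.ndarray  # patients in ward at the end of each cycle
    deaths_per_cycle: np.ndarray
    admissions_per_cycle: np.ndarray
    stock: dict[str, np.ndarray]  # end-of-cycle stock per drug
    dispensed: dict[str, float]
    restocked: dict[str, float]
    initial_stock: dict[str, float]
    final_stock: dict[str, float]
    restock_cycles: list[int]
    shortage_refusals: int
    staff_refusals: int
    untreated_patient_cycles: int

    def summary(self) -> dict:
        """Flat per-trial summary used by results documents and CSV export."""
        complicated = self.admissions - self.cases.get(UNCOMPLICATED, 0)
        return {
            "seed": self.seed,
            "admissions": self.admissions,
            "discharges": self.discharges,
            "deaths": self.deaths,
            "complicated_admissions": complicated,
            "mortality_rate_complicated_pct": (
                100.0 * self.deaths / complicated if complicated else None
            ),
            "mean_census": float(self.census.mean()) if len(self.census) else 0.0,
            "admissions_per_month": self.admissions
            / (self.horizon_cycles / (30 * CYCLES_PER_DAY)),
            "shortage_refusals": self.shortage_refusals,
            "staff_refusals": self.staff_refusals,
        }


def make_rng_streams(seed: int) -> tuple[np.random.Generator, np.random.Generator]:
    """Arrival and survival RNG streams for one trial seed."""
    arrival_ss, survival_ss = np.random.SeedSequence(seed).spawn(2)
    return np.random.default_rng(arrival_ss), np.random.default_rng(survival_ss)


# ---------------------------------------------------------------------------
# The four cycle steps
# ---------------------------------------------------------------------------


def step_admission(
    state: WardState, config: SimulationConfig, rng: np.random.Generator
) -> Optional[Patient]:
    """Admit at most one patient this cycle (Bernoulli on the shift rate)."""
    shift = state.shift()
    if rng.random() >= shift.admission_probability:
        return None
    conditions: dict[str, float] = {}
    if config.multi_morbidity:
        for c in config.complications:
            if rng.random() < c.incidence_pct / 100.0:
                conditions[c.name] = sample_severity(state._severity[c.name], rng)
    else:
        u = rng.random()
        acc = 0.0
        for c in config.complications:
            acc += c.incidence_pct / 100.0
            if u < acc:
                conditions[c.name] = sample_severity(state._severity[c.name], rng)
                break
    if conditions:
        # entry plan of the most severe condition
        worst = max(conditions, key=lambda k: conditions[k])
        plan_id = next(c.entry_plan for c in config.complications if c.name == worst)
        for name in conditions:
            state.cases[name] += 1
    else:
        plan_id = config.uncomplicated_plan
        state.cases[UNCOMPLICATED] += 1
    pat = Patient(state.next_patient_id, state.cycle, conditions, plan_id)
    state.next_patient_id += 1
    state.patients.append(pat)
    state.admissions += 1
    return pat


def assign_plans(state: WardState) -> list[Patient]:
    """Advance completed plans to successors; discharge finished patients.

    Returns the patients discharged alive this cycle.
    """
    discharged: list[Patient] = []
    remaining: list[Patient] = []
    for pat in state.patients:
        plan = state._plans[pat.plan_id]
        if pat.progress >= plan.duration:
            _release_holds(pat)
            if plan.successor is not None:
                pat.plan_id = plan.successor
                pat.progress = 0
                remaining.append(pat)
            else:
                state.discharges += 1
                discharged.append(pat)
        else:
            remaining.append(pat)
    state.patients = remaining
    return discharged


def _cycle_demands(plan: TreatmentPlan, progress: int) -> tuple[dict[str, float], int, int]:
    """Resources the plan demands at this progress point."""
    drugs = {
        name: d.dose
        for name, d in plan.drugs.items()
        if d.dose > 0 and progress % d.frequency == 0
    }
    nurses = plan.nurses.count if progress % plan.nurses.frequency == 0 else 0
    doctors = plan.doctors.count if progress % plan.doctors.frequency == 0 else 0
    return drugs, nurses, doctors


def _release_holds(pat: Patient) -> None:
    pat.held_nurses = 0
    pat.held_doctors = 0


def allocate_resources(
    state: WardState, config: SimulationConfig
) -> tuple[list[Patient], list[Patient]]:
    """Greedy sickest-first allocation; all-or-nothing per patient.

    Patients are visited in strictly descending composite mortality (ties
    broken by earlier admission, then id).  A patient is treated only if
    every drug dose and staff unit her plan demands this cycle is
    available; otherwise nothing is taken and she goes untreated.
    """
    shift = state.shift()
    held_n, held_d = state.held_totals()
    avail_nurses = max(shift.nurses - held_n, 0)
    avail_doctors = max(shift.doctors - held_d, 0)

    order = sorted(
        state.patients, key=lambda p: (-p.composite(), p.admission_cycle, p.id)
    )
    treated: list[Patient] = []
    untreated: list[Patient] = []
    transient_n = transient_d = new_hold_n = new_hold_d = 0
    for pat in order:
        plan = state._plans[pat.plan_id]
        drugs, nurses, doctors = _cycle_demands(plan, pat.progress)
        need_n = max(nurses - pat.held_nurses, 0)
        need_d = max(doctors - pat.held_doctors, 0)
        drug_ok = all(state.inventory[d] + 1e-9 >= dose for d, dose in drugs.items())
        staff_ok = need_n <= avail_nurses and need_d <= avail_doctors
        if drug_ok and staff_ok:
            for d, dose in drugs.items():
                before = state.inventory[d]
                after = max(before - dose, 0.0)
                state.inventory[d] = after
                state.dispensed[d] += before - after
            avail_nurses -= need_n
            avail_doctors -= need_d
            if plan.nurses.consecutive_hold and nurses:
                pat.held_nurses = nurses
                new_hold_n += need_n
            else:
                transient_n += need_n
            if plan.doctors.consecutive_hold and doctors:
                pat.held_doctors = doctors
                new_hold_d += need_d
            else:
                transient_d += need_d
            treated.append(pat)
        else:
            if not drug_ok:
                state.shortage_refusals += 1
            if not staff_ok:
                state.staff_refusals += 1
            untreated.append(pat)
    state.untreated_patient_cycles += len(untreated)
    state.last_allocation = {
        "cycle": state.cycle,
        "shift_nurses": shift.nurses,
        "shift_doctors": shift.doctors,
        "held_nurses_start": held_n,
        "held_doctors_start": held_d,
        "transient_nurses": transient_n,
        "transient_doctors": transient_d,
        "new_hold_nurses": new_hold_n,
        "new_hold_doctors": new_hold_d,
    }
    return treated, untreated


def apply_dynamics(
    state: WardState, treated: list[Patient], untreated: list[Patient]
) -> None:
    """Treated conditions decay; untreated conditions deteriorate."""
    for pat in treated:
        eff = state._eff[pat.plan_id]
        if pat.conditions:
            for name in pat.conditions:
                pat.conditions[name] = apply_treatment_cycle(pat.conditions[name], eff)
        pat.untreated_counter = 0
        pat.progress += 1
    for pat in untreated:
        pat.untreated_counter += 1
        if pat.conditions:
            c = pat.untreated_counter
            for name in pat.conditions:
                det = DeteriorationParams(rate=state._det[name], untreated_cycles=c)
                pat.conditions[name] = apply_deterioration_cycle(pat.conditions[name], det)


def evaluate_survival(state: WardState, rng: np.random.Generator) -> list[Patient]:
    """Draw survival for every patient in the ward; returns this cycle's deaths.

    Each patient's composite mortality is her chance of dying over the
    *remaining* stay, so the per-cycle draw uses the scaled probability
    with n = remaining cycles.  Dead patients release their held staff
    immediately for reallocation next cycle.
    """
    died: list[Patient] = []
    survivors: list[Patient] = []
    for pat in state.patients:
        p_c = pat.composite()
        if p_c > 0.0:
            p_cycle = scaled_cycle_mortality(p_c, state.remaining_stay(pat))
            if rng.random() <= p_cycle:
                pat.alive = False
                _release_holds(pat)
                state.deaths += 1
                worst = max(pat.conditions, key=lambda k: pat.conditions[k])
                state.deaths_by_complication[worst] += 1
                died.append(pat)
                continue
        survivors.append(pat)
    state.patients = survivors
    return died


def restock_and_advance(state: WardState, config: SimulationConfig) -> bool:
    """Restock on schedule, then advance the clock.  Returns True on restock.

    Cycle numbering is 1-based for the restocking schedule: with the
    default monthly interval (2880 cycles) a 90-day run restocks at
    cycles 2880, 5760 and 8640.  Transient staff return to the pool
    implicitly — only ``consecutive_hold`` staff persist on patients.
    """
    restocked = False
    if (state.cycle + 1) % config.restock_interval == 0:
        for drug, spec in config.inventory.items():
            if spec.restock and spec.restock_amount > 0:
                state.inventory[drug] += spec.restock_amount
                state.restocked[drug] += spec.restock_amount
        restocked = True
    state.cycle += 1
    return restocked


# ---------------------------------------------------------------------------
# Trial drivers
# ---------------------------------------------------------------------------


def run_trial(
    config: SimulationConfig,
    seed: int,
    record_trajectories: bool = True,
) -> TrialResult:
    """Run one seeded trial over the configured horizon."""
    arrival_rng, survival_rng = make_rng_streams(seed)
    state = WardState(config=config)
    horizon = config.horizon_cycles
    census = np.zeros(horizon, dtype=np.int32) if record_trajectories else np.zeros(0)
    deaths_pc = np.zeros(horizon, dtype=np.int16) if record_trajectories else np.zeros(0)
    adm_pc = np.zeros(horizon, dtype=np.int8) if record_trajectories else np.zeros(0)
    stock_traj = (
        {d: np.zeros(horizon) for d in config.inventory} if record_trajectories else {}
    )
    initial_stock = dict(state.inventory)
    restock_cycles: list[int] = []

    for t in range(horizon):
        admitted = step_admission(state, config, arrival_rng)
        assign_plans(state)
        treated, untreated = allocate_resources(state, config)
        apply_dynamics(state, treated, untreated)
        died = evaluate_survival(state, survival_rng)
        if restock_and_advance(state, config):
            restock_cycles.append(t + 1)
        if record_trajectories:
            census[t] = len(state.patients)
            deaths_pc[t] = len(died)
            adm_pc[t] = 1 if admitted is not None else 0
            for d in stock_traj:
                stock_traj[d][t] = state.inventory[d]

    return TrialResult(
        seed=seed,
        horizon_cycles=horizon,
        admissions=state.admissions,
        discharges=state.discharges,
        deaths=state.deaths,
        cases=dict(state.cases),
        deaths_by_complication=dict(state.deaths_by_complication),
        final_census=len(state.patients),
        census=census,
        deaths_per_cycle=deaths_pc,
        admissions_per_cycle=adm_pc,
        stock=stock_traj,
        dispensed=dict(state.dispensed),
        restocked=dict(state.restocked),
        initial_stock=initial_stock,
        final_stock=dict(state.inventory),
        restock_cycles=restock_cycles,
        shortage_refusals=state.shortage_refusals,
        staff_refusals=state.staff_refusals,
        untreated_patient_cycles=state.untreated_patient_cycles,
    )


def run_trials(
    config: SimulationConfig,
    n_trials: int | None = None,
    base_seed: int | None = None,
    record_trajectories: bool = True,
) -> list[TrialResult]:
    """Run replicate trials; trial i uses seed = base_seed + i."""
    n = config.n_trials if n_trials is None else n_trials
    if n < 1:
        raise ValueError("n_trials must be >= 1")
    s0 = config.base_seed if base_seed is None else base_seed
    return [
        run_trial(config, s0 + i, record_trajectories=record_trajectories)
        for i in range(n)
    ]
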