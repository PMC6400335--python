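"""Tests of the four-step cycle loop: admission, allocation, survival, restock."""

import math

import numpy as np
import pytest

from wardsim.fixtures import default_mmh_config, random_config, toy_cohort, toy_config, FixtureSpec
from wardsim.io_config import DrugDemand, StaffDemand, TreatmentPlan
from wardsim.model_core import scaled_cycle_mortality
from wardsim.ward_engine import (
    WardState,
    allocate_resources,
    apply_dynamics,
    assign_plans,
    evaluate_survival,
    make_rng_streams,
    restock_and_advance,
    run_trial,
    run_trials,
    step_admission,
)


def _staff_only_plan(duration=8, nurses=1, doctors=0, efficacy=0.5, **kw):
    return TreatmentPlan(
        id="plan", duration=duration, drugs={},
        nurses=StaffDemand(count=nurses, frequency=1),
        doctors=StaffDemand(count=doctors, frequency=1),
        efficacy=efficacy, **kw,
    )


# ---------------------------------------------------------------------------
# admission
# ---------------------------------------------------------------------------


def test_zero_admission_probability_admits_nobody():
    cfg = toy_config(admission_probability=0.0, horizon_cycles=500)
    res = run_trial(cfg, seed=3)
    assert res.admissions == 0 and res.deaths == 0


def test_certain_admission_admits_every_cycle():
    cfg = toy_config(admission_probability=1.0, horizon_cycles=96, nurses=50,
                     doctors=50)
    res = run_trial(cfg, seed=0)
    assert res.admissions == 96  # exactly one per cycle


def test_admission_count_is_binomial():
    """Counts over many cycles match the Bernoulli(p_shift) expectation."""
    p = 0.4
    cfg = toy_config(admission_probability=p, horizon_cycles=9600, nurses=0,
                     doctors=0, severity_mean=0.001, deterioration_rate=1e9)
    res = run_trial(cfg, seed=11, record_trajectories=False)
    n = cfg.horizon_cycles
    assert abs(res.admissions - n * p) < 3 * math.sqrt(n * p * (1 - p)) + 1
    # complication mixture: about half of admissions complicated (50% incidence)
    complicated = res.admissions - res.cases["uncomplicated"]
    assert abs(complicated - 0.5 * res.admissions) < 3 * math.sqrt(res.admissions * 0.25)


# ---------------------------------------------------------------------------
# plan chaining & discharge
# ---------------------------------------------------------------------------


def test_plan_chain_discharges_after_total_treated_cycles():
    """A 4+4 chain discharges after exactly 8 treated cycles."""
    chain = [
        TreatmentPlan(id="first", duration=4, efficacy=0.5,
                      nurses=StaffDemand(count=1, frequency=1), successor="second"),
        TreatmentPlan(id="second", duration=4, efficacy=0.5,
                      nurses=StaffDemand(count=1, frequency=1)),
    ]
    cfg = toy_config(plan=chain[0], nurses=5, doctors=5, stock={},
                     extra_plans=[chain[1]])
    state = toy_cohort([0.2], config=cfg)
    _, survival_rng = make_rng_streams(0)

    plans_seen = []
    for cycle in range(10):
        assign_plans(state)
        if not state.patients:
            break
        plans_seen.append((cycle, state.patients[0].plan_id, state.patients[0].progress))
        treated, untreated = allocate_resources(state, cfg)
        assert untreated == []
        apply_dynamics(state, treated, untreated)
        restock_and_advance(state, cfg)
    assert state.discharges == 1
    assert cycle == 8  # discharged at the start of the ninth cycle
    assert plans_seen[4] == (4, "second", 0)  # successor activates after 4 cycles


def test_uncomplicated_patient_gets_uncomplicated_plan():
    cfg = toy_config()
    state = WardState(config=cfg)
    arrival, _ = make_rng_streams(1)
    # force admissions until an uncomplicated patient appears
    cfg2 = cfg.model_copy(deep=True)
    for s in cfg2.schedule:
        s.admission_probability = 1.0
    state = WardState(config=cfg2)
    for _ in range(20):
        step_admission(state, cfg2, arrival)
    uncomp = [p for p in state.patients if not p.conditions]
    assert uncomp and all(p.plan_id == cfg2.uncomplicated_plan for p in uncomp)
    assert all(p.composite() == 0.0 for p in uncomp)


# ---------------------------------------------------------------------------
# allocation
# ---------------------------------------------------------------------------


def test_sickest_patient_wins_the_last_doctor():
    cfg = toy_config(nurses=5, doctors=1, stock={},
                     plan=_staff_only_plan(nurses=0, doctors=1))
    state = toy_cohort([0.9, 0.1], config=cfg)
    treated, untreated = allocate_resources(state, cfg)
    assert [p.conditions["c0"] for p in treated] == [0.9]
    assert [p.conditions["c0"] for p in untreated] == [0.1]


def test_missing_drug_blocks_treatment_even_with_staff():
    plan = TreatmentPlan(
        id="plan", duration=8, drugs={"drug": DrugDemand(dose=1.0, frequency=1)},
        nurses=StaffDemand(count=1, frequency=1), efficacy=0.5,
    )
    cfg = toy_config(nurses=3, doctors=3, stock={"drug": 0.0}, plan=plan)
    state = toy_cohort([0.5], config=cfg)
    treated, untreated = allocate_resources(state, cfg)
    assert treated == [] and len(untreated) == 1
    assert state.shortage_refusals == 1


def test_all_or_nothing_leaves_stock_untouched_on_refusal():
    plan = TreatmentPlan(
        id="plan", duration=8,
        drugs={"a": DrugDemand(dose=1.0, frequency=1), "b": DrugDemand(dose=1.0, frequency=1)},
        efficacy=0.5,
    )
    cfg = toy_config(stock={"a": 5.0, "b": 0.0}, plan=plan)
    state = toy_cohort([0.5], config=cfg)
    allocate_resources(state, cfg)
    assert state.inventory["a"] == 5.0  # nothing partially dispensed


def test_ample_resources_treat_entire_cohort():
    cfg = toy_config(nurses=50, doctors=50, stock={"drug": 1e6})
    state = toy_cohort([0.1, 0.2, 0.3, 0.0, 0.5], config=cfg)
    treated, untreated = allocate_resources(state, cfg)
    assert len(treated) == 5 and untreated == []


def test_untreated_counter_resets_on_treatment():
    cfg = toy_config(nurses=0, doctors=0, stock={},
                     plan=_staff_only_plan(nurses=1), deterioration_rate=1e9)
    state = toy_cohort([0.3], config=cfg)
    pat = state.patients[0]
    for _ in range(3):
        treated, untreated = allocate_resources(state, cfg)
        apply_dynamics(state, treated, untreated)
    assert pat.untreated_counter == 3 and pat.progress == 0
    # hire a nurse: treatment resumes, counter resets
    cfg.schedule[0].nurses = 1
    treated, untreated = allocate_resources(state, cfg)
    apply_dynamics(state, treated, untreated)
    assert pat.untreated_counter == 0 and pat.progress == 1


def test_consecutive_hold_reserves_staff_across_cycles():
    plan = TreatmentPlan(
        id="plan", duration=4,
        nurses=StaffDemand(count=2, frequency=1, consecutive_hold=True),
        doctors=StaffDemand(count=1, frequency=1, consecutive_hold=True),
        efficacy=0.1,
    )
    cfg = toy_config(nurses=2, doctors=1, stock={}, plan=plan)
    state = toy_cohort([0.5, 0.4], config=cfg)
    for cycle in range(4):
        assign_plans(state)
        treated, untreated = allocate_resources(state, cfg)
        # held staff fully occupy the pool: second patient can never start
        assert [p.id for p in treated] == [0]
        assert state.patients[0].held_nurses == 2
        assert state.patients[0].held_doctors == 1
        apply_dynamics(state, treated, untreated)
    assign_plans(state)  # plan completes -> holds released, patient discharged
    assert state.patients[0].id == 1
    treated, _ = allocate_resources(state, cfg)
    assert [p.id for p in treated] == [1]


def _brute_force_greedy(patients, stock, nurses, doctors, plans):
    """Independent reimplementation of sickest-first all-or-nothing triage."""
    stock = dict(stock)
    order = sorted(patients, key=lambda p: (-p.composite(), p.admission_cycle, p.id))
    treated = []
    for pat in order:
        plan = plans[pat.plan_id]
        need = {
            d: dd.dose for d, dd in plan.drugs.items()
            if dd.dose > 0 and pat.progress % dd.frequency == 0
        }
        nn = plan.nurses.count if pat.progress % plan.nurses.frequency == 0 else 0
        nd = plan.doctors.count if pat.progress % plan.doctors.frequency == 0 else 0
        nn = max(nn - pat.held_nurses, 0)
        nd = max(nd - pat.held_doctors, 0)
        if all(stock.get(d, 0) + 1e-9 >= v for d, v in need.items()) and nn <= nurses and nd <= doctors:
            for d, v in need.items():
                stock[d] -= v
            nurses -= nn
            doctors -= nd
            treated.append(pat.id)
    return set(treated)


def test_allocation_matches_brute_force_on_small_cohorts(rng):
    """Greedy engine allocation equals the independent triage oracle."""
    for trial in range(120):
        n_pat = int(rng.integers(1, 7))
        plan = TreatmentPlan(
            id="plan", duration=16,
            drugs={"drug": DrugDemand(dose=float(rng.choice([0.5, 1.0, 2.0])),
                                      frequency=int(rng.integers(1, 4)))},
            nurses=StaffDemand(count=int(rng.integers(0, 3)),
                               frequency=int(rng.integers(1, 3))),
            doctors=StaffDemand(count=int(rng.integers(0, 2)),
                                frequency=int(rng.integers(1, 3))),
            efficacy=0.5,
        )
        nurses, doctors = int(rng.integers(0, 4)), int(rng.integers(0, 3))
        stock = {"drug": float(rng.integers(0, 5))}
        cfg = toy_config(nurses=nurses, doctors=doctors, stock=dict(stock), plan=plan)
        sev = rng.uniform(0.01, 0.99, size=n_pat)
        state = toy_cohort(list(sev), config=cfg)
        for p in state.patients:  # randomize progress so frequencies matter
            p.progress = int(rng.integers(0, plan.duration))
        expected = _brute_force_greedy(
            state.patients, stock, nurses, doctors, {"plan": plan}
        )
        treated, _ = allocate_resources(state, cfg)
        assert {p.id for p in treated} == expected


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


def test_zero_mortality_patient_always_survives():
    cfg = toy_config()
    state = toy_cohort([0.0, 0.0, 0.0], config=cfg)
    _, survival = make_rng_streams(0)
    for _ in range(200):
        died = evaluate_survival(state, survival)
        assert died == []
    assert len(state.patients) == 3


def test_near_certain_death_on_last_cycle(rng):
    """p_c = 0.99 with one cycle left kills at frequency 0.99."""
    cfg = toy_config(plan=_staff_only_plan(duration=1, nurses=1))
    deaths = 0
    n = 20_000
    _, survival = make_rng_streams(99)
    for _ in range(n):
        state = toy_cohort([0.99], config=cfg)
        if evaluate_survival(state, survival):
            deaths += 1
    assert abs(deaths / n - 0.99) < 3 * math.sqrt(0.99 * 0.01 / n)


def test_untreated_constant_risk_reproduces_stay_level_mortality():
    """Never-treated patients with negligible deterioration die at p_c over n cycles.

    With no staff the patient's plan never advances, so the remaining
    stay stays at n = 10 and each cycle draws the scaled probability;
    over 10 cycles the cumulative death fraction must equal p_c = 0.2.
    """
    p_c, n_cycles, reps = 0.2, 10, 4000
    plan = _staff_only_plan(duration=n_cycles, nurses=1)
    cfg = toy_config(nurses=0, doctors=0, stock={}, plan=plan,
                     deterioration_rate=1e12)
    deaths = 0
    _, survival = make_rng_streams(123)
    for _ in range(reps):
        state = toy_cohort([p_c], config=cfg)
        for _ in range(n_cycles):
            treated, untreated = allocate_resources(state, cfg)
            apply_dynamics(state, treated, untreated)
            if evaluate_survival(state, survival):
                deaths += 1
                break
    se = math.sqrt(p_c * (1 - p_c) / reps)
    assert abs(deaths / reps - p_c) < 3 * se


def test_death_releases_held_staff():
    plan = TreatmentPlan(
        id="plan", duration=8,
        nurses=StaffDemand(count=1, frequency=1, consecutive_hold=True),
        efficacy=0.0,
    )
    cfg = toy_config(nurses=1, doctors=0, stock={}, plan=plan)
    state = toy_cohort([0.999999], config=cfg)
    treated, untreated = allocate_resources(state, cfg)
    assert state.patients[0].held_nurses == 1
    _, survival = make_rng_streams(5)
    for _ in range(500):
        apply_dynamics(state, treated, untreated)
        if evaluate_survival(state, survival):
            break
        treated, untreated = allocate_resources(state, cfg)
    assert state.deaths == 1
    assert state.held_totals() == (0, 0)


# ---------------------------------------------------------------------------
# restock, shifts, clock
# ---------------------------------------------------------------------------


def test_monthly_restock_fires_three_times_in_90_days():
    cfg = toy_config(admission_probability=0.0, horizon_cycles=8640)
    cfg.inventory["drug"].restock = True
    cfg.inventory["drug"].restock_amount = 7.0
    res = run_trial(cfg, seed=0, record_trajectories=False)
    assert res.restock_cycles == [2880, 5760, 8640]
    assert res.restocked["drug"] == pytest.approx(21.0)


def test_no_restock_stock_is_monotone_nonincreasing():
    cfg = default_mmh_config(horizon_days=5)
    for d in cfg.inventory.values():
        d.restock = False
    res = run_trial(cfg, seed=2)
    for traj in res.stock.values():
        assert np.all(np.diff(traj) <= 1e-12)


def test_shift_lookup_covers_day_with_wraparound(mmh_config):
    by_cycle = [mmh_config.shift_at(c).name for c in range(96)]
    assert by_cycle[24] == "morning" and by_cycle[55] == "morning"
    assert by_cycle[56] == "evening" and by_cycle[87] == "evening"
    # night wraps across midnight
    assert by_cycle[88] == "night" and by_cycle[95] == "night" and by_cycle[0] == "night"
    assert by_cycle[23] == "night"
    # absolute cycles map through the day clock
    assert mmh_config.shift_at(96 + 30).name == "morning"


def test_shift_staffing_switches_at_boundary(mmh_config):
    state = WardState(config=mmh_config)
    state.cycle = 55  # last morning cycle
    assert state.shift().nurses == 5 and state.shift().doctors == 3
    state.cycle = 56  # first evening cycle
    s = state.shift()
    assert (s.nurses, s.doctors, s.admission_probability) == (3, 2, 0.28)


# ---------------------------------------------------------------------------
# whole-trial invariants
# ---------------------------------------------------------------------------


def test_trial_is_deterministic_for_a_seed(mmh_config):
    cfg = mmh_config.model_copy(deep=True)
    cfg.horizon_cycles = 96 * 7
    a = run_trial(cfg, seed=42)
    b = run_trial(cfg, seed=42)
    assert a.summary() == b.summary()
    assert np.array_equal(a.census, b.census)
    assert a.deaths_by_complication == b.deaths_by_complication
    c = run_trial(cfg, seed=43)
    assert not np.array_equal(a.admissions_per_cycle, c.admissions_per_cycle)


def test_tally_consistency_admissions_balance(mmh_config):
    cfg = mmh_config.model_copy(deep=True)
    cfg.horizon_cycles = 96 * 10
    res = run_trial(cfg, seed=9)
    assert res.admissions == res.discharges + res.deaths + res.final_census
    assert sum(res.cases.values()) >= res.admissions  # multi-condition safe
    assert res.deaths == sum(res.deaths_by_complication.values())
    assert res.deaths == int(res.deaths_per_cycle.sum())
    assert res.admissions == int(res.admissions_per_cycle.sum())


def test_stock_ledger_balances(mmh_config):
    cfg = mmh_config.model_copy(deep=True)
    cfg.horizon_cycles = 96 * 30
    res = run_trial(cfg, seed=4)
    for drug in cfg.inventory:
        expected = res.initial_stock[drug] + res.restocked[drug] - res.dispensed[drug]
        assert res.final_stock[drug] == pytest.approx(expected, abs=1e-9)
        assert res.final_stock[drug] >= 0


def test_staff_conservation_every_cycle():
    """Pool draws never exceed availability; held + available = on-shift total."""
    cfg = default_mmh_config(horizon_days=3)
    state = WardState(config=cfg)
    arrival, survival = make_rng_streams(17)
    for _ in range(cfg.horizon_cycles):
        step_admission(state, cfg, arrival)
        assign_plans(state)
        treated, untreated = allocate_resources(state, cfg)
        audit = state.last_allocation
        for kind in ("nurses", "doctors"):
            total = audit[f"shift_{kind}"]
            held0 = audit[f"held_{kind}_start"]
            available = max(total - held0, 0)
            used = audit[f"transient_{kind}"] + audit[f"new_hold_{kind}"]
            assert 0 <= used <= available
            assert available + min(held0, max(total, held0)) == max(total, held0)
        held_n, held_d = state.held_totals()
        assert held_n >= 0 and held_d >= 0
        apply_dynamics(state, treated, untreated)
        evaluate_survival(state, survival)
        restock_and_advance(state, cfg)


def test_run_trials_uses_consecutive_seeds(mmh_config):
    cfg = mmh_config.model_copy(deep=True)
    cfg.horizon_cycles = 96 * 2
    trials = run_trials(cfg, n_trials=3, base_seed=100)
    singles = [run_trial(cfg, seed=100 + i) for i in range(3)]
    for t, s in zip(trials, singles):
        assert t.seed == s.seed and t.summary() == s.summary()


def test_random_configs_run_and_balance():
    """Random configurations run whole trials with exact ledgers and tallies."""
    for seed in (0, 1, 2):
        cfg = random_config(FixtureSpec(seed=seed, richness="scarce"))
        cfg.horizon_cycles = min(cfg.horizon_cycles, 96 * 10)
        res = run_trial(cfg, seed=seed, record_trajectories=False)
        assert res.admissions == res.discharges + res.deaths + res.final_census
        for drug in cfg.inventory:
            expected = (res.initial_stock[drug] + res.restocked[drug]
                        - res.dispensed[drug])
            assert res.final_stock[drug] == pytest.approx(expected, abs=1e-9)
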