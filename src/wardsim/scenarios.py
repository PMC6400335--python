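"""Scenario sweeps: medicine stocks, staffing grids, shift patterns, influx.

Each sweep varies one dimension of a base configuration and reruns the
full three-month simulation over replicate trials.  Trial ``i`` of every
cell uses seed ``base_seed + i`` — common random numbers across cells —
so paired contrasts between cells are sharpened: both cells see the same
arrival sequence and differ only through resource availability.

Outputs are tidy DataFrames (one row per cell per trial) plus per-cell
summaries; plotting is left to the caller.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_config import CYCLES_PER_MONTH, SimulationConfig
from .ward_engine import UNCOMPLICATED, TrialResult, run_trials

__all__ = [
    "SweepSpec",
    "SummaryStats",
    "summarize",
    "sweep_medication",
    "sweep_staffing",
    "sweep_shift_patterns",
    "sweep_admission",
]


@dataclass(frozen=True)
class SweepSpec:
    """Shared settings for a sweep over a base configuration."""

    base_config: SimulationConfig
    n_trials: int = 50
    base_seed: int = 0
    horizon_cycles: int | None = None  # None: base config's horizon (90 days)

    def prepared(self) -> SimulationConfig:
        cfg = self.base_config.model_copy(deep=True)
        if self.horizon_cycles is not None:
            cfg.horizon_cycles = self.horizon_cycles
        return cfg


@dataclass(frozen=True)
class SummaryStats:
    """Aggregate outcome measures over replicate trials."""

    n_trials: int
    deaths_per_trial: tuple[float, ...]
    deaths_mean: float
    deaths_sd: float
    deaths_quartiles: tuple[float, float, float]
    mortality_rate_complicated_pct: float | None
    cfr_pct: dict[str, float | None]
    incidence_pct: dict[str, float | None]
    mean_daily_census: float
    sd_daily_census: float
    admissions_per_month: float


def summarize(trials: list[TrialResult]) -> SummaryStats:
    """Pooled outcome measures across trials.

    Rates follow their definitions exactly: mortality rate is the
    percentage of fatal cases among complicated patients, CFR the
    percentage of fatal cases per complication, incidence the percentage
    of admissions presenting with the complication.  Rates with an empty
    denominator are reported as missing (None), not zero.
    """
    deaths = np.array([t.deaths for t in trials], dtype=float)
    admissions = sum(t.admissions for t in trials)
    complicated = sum(t.admissions - t.cases.get(UNCOMPLICATED, 0) for t in trials)
    comp_names = sorted(
        {n for t in trials for n in t.cases if n != UNCOMPLICATED}
    )
    cases = {n: sum(t.cases.get(n, 0) for t in trials) for n in comp_names}
    cdeaths = {n: sum(t.deaths_by_complication.get(n, 0) for t in trials)
               for n in comp_names}

    census_all = np.concatenate([t.census for t in trials if len(t.census)]) \
        if any(len(t.census) for t in trials) else np.array([0.0])
    months = sum(t.horizon_cycles for t in trials) / CYCLES_PER_MONTH

    return SummaryStats(
        n_trials=len(trials),
        deaths_per_trial=tuple(float(d) for d in deaths),
        deaths_mean=float(deaths.mean()),
        deaths_sd=float(deaths.std(ddof=1)) if len(deaths) > 1 else 0.0,
        deaths_quartiles=tuple(float(q) for q in np.percentile(deaths, [25, 50, 75])),
        mortality_rate_complicated_pct=(
            100.0 * float(deaths.sum()) / complicated if complicated else None
        ),
        cfr_pct={
            n: (100.0 * cdeaths[n] / cases[n] if cases[n] else None)
            for n in comp_names
        },
        incidence_pct={
            n: (100.0 * cases[n] / admissions if admissions else None)
            for n in comp_names
        },
        mean_daily_census=float(census_all.mean()),
        sd_daily_census=float(census_all.std(ddof=0)),
        admissions_per_month=admissions / months if months else math.nan,
    )


def _tidy_rows(trials: list[TrialResult], cell: dict) -> list[dict]:
    return [dict(cell, trial=i, **t.summary()) for i, t in enumerate(trials)]


def _run_cell(cfg: SimulationConfig, spec: SweepSpec) -> list[TrialResult]:
    return run_trials(cfg, n_trials=spec.n_trials, base_seed=spec.base_seed,
                      record_trajectories=False)


# ---------------------------------------------------------------------------
# Medication sweep
# ---------------------------------------------------------------------------

#: the other drug is pinned while one is swept, to isolate its effect
MEDICATION_CONTROLS = {
    "oxytocin": ("hydralazine", 11.0),
    "hydralazine": ("oxytocin", 200.0),
}

DEFAULT_STOCK_GRIDS = {
    "oxytocin": (0.0, 50.0, 100.0, 150.0, 200.0),
    "hydralazine": (0.0, 5.0, 10.0, 15.0, 20.0, 25.0),
}


def sweep_medication(
    spec: SweepSpec,
    drug: str,
    stock_levels: tuple[float, ...] | None = None,
    restock_options: tuple[bool, ...] = (True, False),
) -> pd.DataFrame:
    """Vary one drug's initial stock with and without monthly restocking.

    While sweeping oxytocin, hydralazine is held at 11 packs with no
    restock; while sweeping hydralazine, oxytocin is held at 200 packs
    with no restock.  Restock shipments equal the initial stock level.
    """
    if drug not in MEDICATION_CONTROLS:
        raise ValueError(f"unknown sweep drug {drug!r}")
    levels = DEFAULT_STOCK_GRIDS[drug] if stock_levels is None else stock_levels
    control_drug, control_level = MEDICATION_CONTROLS[drug]

    rows: list[dict] = []
    for level in levels:
        for restock in restock_options:
            cfg = spec.prepared()
            inv = cfg.inventory[drug]
            inv.initial = float(level)
            inv.restock = bool(restock)
            inv.restock_amount = float(level) if restock else 0.0
            if control_drug in cfg.inventory:
                ctl = cfg.inventory[control_drug]
                ctl.initial = control_level
                ctl.restock = False
                ctl.restock_amount = 0.0
            trials = _run_cell(cfg, spec)
            rows.extend(
                _tidy_rows(trials, {"drug": drug, "stock": level, "restock": restock})
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Staffing sweeps
# ---------------------------------------------------------------------------


def sweep_staffing(
    spec: SweepSpec,
    nurse_range: range = range(0, 11),
    doctor_range: range = range(0, 11),
) -> pd.DataFrame:
    """Grid over (nurses, doctors), held constant across all shifts."""
    rows: list[dict] = []
    for n in nurse_range:
        for d in doctor_range:
            cfg = spec.prepared()
            for s in cfg.schedule:
                s.nurses = int(n)
                s.doctors = int(d)
            trials = _run_cell(cfg, spec)
            rows.extend(_tidy_rows(trials, {"nurses": n, "doctors": d}))
    return pd.DataFrame(rows)


def _shift_patterns(cfg: SimulationConfig) -> dict[str, dict[str, tuple[int, int]]]:
    """Named per-shift (nurses, doctors) patterns relative to the current one."""
    current = {s.name: (s.nurses, s.doctors) for s in cfg.schedule}
    return {
        "current": current,
        "one_fewer_each": {
            k: (max(n - 1, 0), max(d - 1, 0)) for k, (n, d) in current.items()
        },
        "five_nurses_all_shifts": {k: (5, d) for k, (n, d) in current.items()},
        "three_doctors_all_shifts": {k: (n, 3) for k, (n, d) in current.items()},
    }


def sweep_shift_patterns(
    spec: SweepSpec,
    patterns: dict[str, dict[str, tuple[int, int]]] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Compare named per-shift staffing patterns against the current one.

    Returns (tidy per-trial rows, comparison table).  The comparison is
    a Welch two-tailed t-test on per-trial death counts of each pattern
    against "current"; the table reports the statistic and p-value, not
    a verdict.
    """
    base = spec.prepared()
    patterns = _shift_patterns(base) if patterns is None else patterns

    rows: list[dict] = []
    deaths_by_pattern: dict[str, np.ndarray] = {}
    for name, staffing in patterns.items():
        cfg = spec.prepared()
        for s in cfg.schedule:
            n, d = staffing[s.name]
            s.nurses, s.doctors = int(n), int(d)
        trials = _run_cell(cfg, spec)
        deaths_by_pattern[name] = np.array([t.deaths for t in trials], dtype=float)
        rows.extend(_tidy_rows(trials, {"pattern": name}))

    comparisons = []
    ref = deaths_by_pattern.get("current")
    for name, vals in deaths_by_pattern.items():
        if name == "current" or ref is None:
            continue
        t_stat, p_val = stats.ttest_ind(vals, ref, equal_var=False)
        comparisons.append({
            "pattern": name,
            "vs": "current",
            "mean_deaths": float(vals.mean()),
            "mean_deaths_current": float(ref.mean()),
            "t_statistic": float(t_stat),
            "p_value": float(p_val),
        })
    return pd.DataFrame(rows), pd.DataFrame(comparisons)


# ---------------------------------------------------------------------------
# Admission-rate sweep
# ---------------------------------------------------------------------------


def sweep_admission(
    spec: SweepSpec,
    multipliers: tuple[float, ...] = (0.5, 1.0, 1.5),
) -> pd.DataFrame:
    """Scale every shift's admission probability by each multiplier.

    Probabilities exceeding 1 are clipped to 1 with a warning.  The key
    outcome per cell is the mortality rate among complicated patients.
    """
    rows: list[dict] = []
    for m in multipliers:
        cfg = spec.prepared()
        for s in cfg.schedule:
            scaled = s.admission_probability * m
            if scaled > 1.0:
                warnings.warn(
                    f"admission probability {scaled:.3f} on shift {s.name!r} "
                    "clipped to 1.0",
                    stacklevel=2,
                )
                scaled = 1.0
            s.admission_probability = scaled
        trials = _run_cell(cfg, spec)
        rows.extend(_tidy_rows(trials, {"multiplier": m}))
    return pd.DataFrame(rows)
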