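"""Calibration of the ward model to target outcome rates.

Three quantities are calibrated, in this order:

1. **Severity SDs** — analytic: the severe-maternal-outcome mortality is
   placed two standard deviations above the severity mean, so
   sd = (smo - mean) / 2.
2. **Treatment efficacies** — analytic: eta is solved so the mean case
   of each complication decays geometrically to the 1e-10 mortality
   floor exactly at the end of its plan chain.
3. **Deterioration rates** — simulation-based: per complication, a
   monotone bisection on log10(lambda) drives the simulated case
   fatality rate to the target.  The simulated CFR is a noisy but
   monotone-decreasing function of lambda (slower deterioration means
   fewer deaths), so bisection with common random numbers across
   evaluations converges despite Monte-Carlo noise.

Incidence rates are inputs (the admission mixture), not fitted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_config import SimulationConfig
from .model_core import calibrate_efficacy, derive_severity_sd
from .ward_engine import TrialResult, run_trials

__all__ = [
    "CalibrationTargets",
    "CalibrationResult",
    "simulated_cfrs",
    "fit_deterioration_rates",
    "build_calibrated_config",
    "calibration_report",
]

LOG_LAMBDA_BRACKET = (-2.0, 4.0)  # lambda in [1e-2, 1e4]


@dataclass(frozen=True)
class CalibrationTargets:
    """Per-complication targets, in percent, plus fitting settings."""

    cfr_pct: dict[str, float]
    incidence_pct: dict[str, float] = field(default_factory=dict)
    smo_mortality: float | None = None
    tolerance_rel_pct: float = 10.0  # stop when |CFR - target| <= tol% of target
    mc_trials: int = 50
    horizon_cycles: int | None = None  # None: use the config's horizon
    max_iter: int = 18

    def __post_init__(self) -> None:
        for name, v in self.cfr_pct.items():
            if not (0.0 <= v < 100.0):
                raise ValueError(f"target CFR for {name!r} must be in [0, 100)")
        if self.tolerance_rel_pct <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class CalibrationResult:
    fitted_rates: dict[str, float]
    achieved_cfr_pct: dict[str, float]
    achieved_cfr_se_pct: dict[str, float]
    converged: dict[str, bool]
    trace: dict[str, list[tuple[float, float]]]  # name -> [(lambda, cfr%), ...]
    bracket: tuple[float, float] = LOG_LAMBDA_BRACKET


def _cfr_from_trials(trials: list[TrialResult], name: str) -> tuple[float, float]:
    """Pooled CFR (%) for one complication and its Monte-Carlo SE."""
    per_trial = []
    deaths = cases = 0
    for t in trials:
        c = t.cases.get(name, 0)
        d = t.deaths_by_complication.get(name, 0)
        deaths += d
        cases += c
        if c:
            per_trial.append(100.0 * d / c)
    if cases == 0:
        return math.nan, math.nan
    cfr = 100.0 * deaths / cases
    se = float(np.std(per_trial, ddof=1) / math.sqrt(len(per_trial))) if len(per_trial) > 1 else math.nan
    return cfr, se


def simulated_cfrs(
    config: SimulationConfig,
    n_trials: int,
    base_seed: int,
    horizon_cycles: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Simulate and return {complication: (CFR %, SE %)}."""
    cfg = config.model_copy(deep=True)
    if horizon_cycles is not None:
        cfg.horizon_cycles = horizon_cycles
    trials = run_trials(cfg, n_trials=n_trials, base_seed=base_seed,
                        record_trajectories=False)
    return {c.name: _cfr_from_trials(trials, c.name) for c in cfg.complications}


def fit_deterioration_rates(
    config: SimulationConfig,
    targets: CalibrationTargets,
    base_seed: int | None = None,
) -> CalibrationResult:
    """Fit per-complication deterioration rates by bisection on log lambda.

    Each complication is fitted in turn with the others held at their
    current (possibly already-updated) rates.  Every objective
    evaluation reuses the same trial seeds (common random numbers), so
    the CFR-vs-lambda curve seen by the bisection is a fixed, monotone
    step function and the search terminates cleanly.
    """
    cfg = config.model_copy(deep=True)
    if targets.horizon_cycles is not None:
        cfg.horizon_cycles = targets.horizon_cycles
    seed = cfg.base_seed if base_seed is None else base_seed

    fitted: dict[str, float] = {}
    achieved: dict[str, float] = {}
    achieved_se: dict[str, float] = {}
    converged: dict[str, bool] = {}
    trace: dict[str, list[tuple[float, float]]] = {}
    lo, hi = LOG_LAMBDA_BRACKET

    def evaluate(name: str, log_lam: float) -> tuple[float, float]:
        for c in cfg.complications:
            if c.name == name:
                c.deterioration_rate = 10.0**log_lam
        out = simulated_cfrs(cfg, targets.mc_trials, seed)
        return out[name]

    for comp in cfg.complications:
        name = comp.name
        if name not in targets.cfr_pct:
            continue
        target = targets.cfr_pct[name]
        tol = targets.tolerance_rel_pct / 100.0 * max(target, 1e-12)
        trace[name] = []

        cfr_lo, _ = evaluate(name, lo)  # fastest deterioration -> highest CFR
        trace[name].append((10.0**lo, cfr_lo))
        cfr_hi, se_hi = evaluate(name, hi)  # slowest -> lowest CFR
        trace[name].append((10.0**hi, cfr_hi))

        if target <= 0.0 or target > cfr_lo or (not math.isnan(cfr_hi) and target < cfr_hi):
            # unreachable inside the bracket: keep the closer endpoint, flag it
            if not math.isnan(cfr_hi) and abs(cfr_hi - target) <= abs(cfr_lo - target):
                best_log, best_cfr, best_se = hi, cfr_hi, se_hi
            else:
                best_log, best_cfr, best_se = lo, cfr_lo, math.nan
            fitted[name] = 10.0**best_log
            achieved[name] = best_cfr
            achieved_se[name] = best_se
            converged[name] = False
        else:
            a, b = lo, hi
            best_log, best_cfr, best_se = a, cfr_lo, math.nan
            ok = False
            for _ in range(targets.max_iter):
                mid = 0.5 * (a + b)
                cfr_mid, se_mid = evaluate(name, mid)
                trace[name].append((10.0**mid, cfr_mid))
                if math.isnan(cfr_mid):
                    break
                if abs(cfr_mid - target) < abs(best_cfr - target):
                    best_log, best_cfr, best_se = mid, cfr_mid, se_mid
                if abs(cfr_mid - target) <= tol:
                    ok = True
                    break
                if cfr_mid > target:
                    a = mid  # deterioration too fast: raise lambda
                else:
                    b = mid
            fitted[name] = 10.0**best_log
            achieved[name] = best_cfr
            achieved_se[name] = best_se
            converged[name] = ok
        # keep the best rate in place while fitting the remaining complications
        for c in cfg.complications:
            if c.name == name:
                c.deterioration_rate = fitted[name]

    return CalibrationResult(
        fitted_rates=fitted,
        achieved_cfr_pct=achieved,
        achieved_cfr_se_pct=achieved_se,
        converged=converged,
        trace=trace,
    )


def build_calibrated_config(
    raw_config: SimulationConfig,
    targets: CalibrationTargets,
    base_seed: int | None = None,
    fit_rates: bool = True,
) -> SimulationConfig:
    """Full calibration pipeline; returns a new config with provenance.

    Severity SDs come from the SMO rule, efficacies from the analytic
    cure-on-time rule over each complication's plan chain, and
    deterioration rates from the simulated-CFR bisection (skippable via
    ``fit_rates`` when only the analytic stages are wanted).
    """
    cfg = raw_config.model_copy(deep=True)
    provenance: dict[str, dict] = {"severity_sd": {}, "efficacy": {}, "deterioration_rate": {}}

    smo = targets.smo_mortality
    for comp in cfg.complications:
        smo_val = comp.smo_mortality if smo is None else smo
        if smo_val is None:
            raise ValueError(
                f"complication {comp.name!r}: smo_mortality missing from both "
                "config and targets"
            )
        comp.smo_mortality = smo_val
        comp.severity_sd = derive_severity_sd(comp.severity_mean, smo_val)
        provenance["severity_sd"][comp.name] = {
            "value": comp.severity_sd, "rule": "(smo - mean) / 2", "smo": smo_val,
        }

    for comp in cfg.complications:
        duration = cfg.chain_cycles(comp.entry_plan)
        eff = calibrate_efficacy(comp.severity_mean, duration)
        cur = comp.entry_plan
        while cur is not None:
            plan = cfg.plan(cur)
            plan.efficacy = eff.efficacy
            cur = plan.successor
        provenance["efficacy"][comp.name] = {
            "value": eff.efficacy, "chain_cycles": duration,
            "rule": "1 - (1e-10 / mean)**(1/duration)",
        }

    if fit_rates:
        result = fit_deterioration_rates(cfg, targets, base_seed=base_seed)
        for comp in cfg.complications:
            if comp.name in result.fitted_rates:
                comp.deterioration_rate = result.fitted_rates[comp.name]
                provenance["deterioration_rate"][comp.name] = {
                    "value": comp.deterioration_rate,
                    "target_cfr_pct": targets.cfr_pct[comp.name],
                    "achieved_cfr_pct": result.achieved_cfr_pct[comp.name],
                    "converged": result.converged[comp.name],
                }

    cfg.calibration = {
        "targets_cfr_pct": dict(targets.cfr_pct),
        "mc_trials": targets.mc_trials,
        "provenance": provenance,
    }
    return cfg


def _box_stats(values: np.ndarray) -> dict[str, float]:
    """Box-plot summary: median, quartiles, whiskers (1.5 IQR), outliers."""
    if len(values) == 0:
        return {k: math.nan for k in
                ("median", "q1", "q3", "whisker_low", "whisker_high", "n_outliers")}
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo_fence, hi_fence = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = values[(values >= lo_fence) & (values <= hi_fence)]
    return {
        "median": float(med), "q1": float(q1), "q3": float(q3),
        "whisker_low": float(inside.min()) if len(inside) else math.nan,
        "whisker_high": float(inside.max()) if len(inside) else math.nan,
        "n_outliers": int(len(values) - len(inside)),
    }


def calibration_report(
    config: SimulationConfig,
    targets: CalibrationTargets,
    n_trials: int | None = None,
    base_seed: int | None = None,
) -> pd.DataFrame:
    """Simulated CFR and incidence distributions vs targets, per complication.

    One row per complication per metric ("cfr" / "incidence"); values in
    percent over ``n_trials`` replicate runs, summarized as box-plot
    statistics (mean is inclusive of outliers).
    """
    n = targets.mc_trials if n_trials is None else n_trials
    seed = config.base_seed if base_seed is None else base_seed
    trials = run_trials(config, n_trials=n, base_seed=seed, record_trajectories=False)

    rows = []
    for comp in config.complications:
        name = comp.name
        cfr_vals, inc_vals = [], []
        for t in trials:
            cases = t.cases.get(name, 0)
            if cases:
                cfr_vals.append(100.0 * t.deaths_by_complication.get(name, 0) / cases)
            if t.admissions:
                inc_vals.append(100.0 * cases / t.admissions)
        for metric, vals, target in (
            ("cfr", np.asarray(cfr_vals), targets.cfr_pct.get(name)),
            ("incidence", np.asarray(inc_vals), targets.incidence_pct.get(name)),
        ):
            row = {
                "complication": name,
                "metric": metric,
                "target_pct": target,
                "mean_pct": float(vals.mean()) if len(vals) else math.nan,
                "n_trials_with_cases": len(vals),
            }
            row.update({f"{k}_pct" if k != "n_outliers" else k: v
                        for k, v in _box_stats(vals).items()})
            rows.append(row)
    return pd.DataFrame(rows)
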