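"""Configuration schema, validation, and results serialization.

A simulation is fully described by one JSON document: the shift schedule
(staffing and admission probability per shift), the complication mix
(incidence, severity distribution, deterioration rate, entry treatment
plan), the treatment-plan library, the medicine inventory with its
restocking rule, and run settings (horizon, trials, seed).  The schema is
strict — unknown fields are rejected — so a typo in a config fails fast
with a field path instead of silently simulating the wrong ward.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Any, Optional

import pandas as pd
from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

CYCLES_PER_DAY = 96
CYCLES_PER_MONTH = 30 * CYCLES_PER_DAY  # one "month" = 30 days = 2880 cycles

__all__ = [
    "ConfigError",
    "DrugDemand",
    "StaffDemand",
    "TreatmentPlan",
    "Complication",
    "Shift",
    "DrugStock",
    "SimulationConfig",
    "load_config",
    "loads_config",
    "dump_config",
    "config_hash",
    "write_results",
    "read_results",
    "export_csv",
    "CYCLES_PER_DAY",
    "CYCLES_PER_MONTH",
]


class ConfigError(ValueError):
    """Configuration failed validation; message carries field paths."""


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class DrugDemand(_Strict):
    """Dose (in packs, fractions allowed) demanded every ``frequency`` cycles."""

    dose: float = Field(ge=0)
    frequency: int = Field(ge=1)


class StaffDemand(_Strict):
    """Staff units demanded every ``frequency`` cycles of plan progress.

    ``consecutive_hold`` reserves the units with the patient between
    visits until the plan completes (or the patient dies/discharges),
    instead of returning them to the pool each cycle.
    """

    count: int = Field(ge=0, default=0)
    frequency: int = Field(ge=1, default=1)
    consecutive_hold: bool = False


class TreatmentPlan(_Strict):
    id: str
    duration: int = Field(ge=1, description="treated cycles until completion")
    drugs: dict[str, DrugDemand] = Field(default_factory=dict)
    nurses: StaffDemand = Field(default_factory=StaffDemand)
    doctors: StaffDemand = Field(default_factory=StaffDemand)
    efficacy: float = Field(ge=0, le=1)
    successor: Optional[str] = None


class Complication(_Strict):
    name: str
    incidence_pct: float = Field(gt=0, lt=100, description="% of admissions")
    severity_mean: float = Field(gt=0, lt=1)
    severity_sd: Optional[float] = Field(default=None, gt=0)
    smo_mortality: Optional[float] = Field(default=None, gt=0, lt=1)
    deterioration_rate: float = Field(gt=0)
    entry_plan: str
    illustrative: bool = False

    @model_validator(mode="after")
    def _sd_available(self) -> "Complication":
        if self.severity_sd is None and self.smo_mortality is None:
            raise ValueError(
                f"complication {self.name!r}: either severity_sd or smo_mortality required"
            )
        if self.smo_mortality is not None and self.smo_mortality <= self.severity_mean:
            raise ValueError(
                f"complication {self.name!r}: smo_mortality must exceed severity_mean"
            )
        return self


class Shift(_Strict):
    name: str
    start_cycle: int = Field(ge=0, lt=CYCLES_PER_DAY, description="cycle of day the shift starts")
    duration: int = Field(ge=1, le=CYCLES_PER_DAY)
    nurses: int = Field(ge=0)
    doctors: int = Field(ge=0)
    admission_probability: float = Field(ge=0, le=1)


class DrugStock(_Strict):
    initial: float = Field(ge=0, description="packs on hand at cycle 0")
    restock_amount: float = Field(ge=0, default=0.0, description="packs added per restock")
    restock: bool = True


class SimulationConfig(_Strict):
    schema_version: int = 1
    schedule: list[Shift]
    complications: list[Complication]
    uncomplicated_pct: float = Field(gt=0, le=100)
    uncomplicated_plan: str
    plans: list[TreatmentPlan]
    inventory: dict[str, DrugStock]
    restock_interval: int = Field(default=CYCLES_PER_MONTH, ge=1)
    horizon_cycles: int = Field(default=3 * CYCLES_PER_MONTH, ge=1)
    n_trials: int = Field(default=50, ge=1)
    base_seed: int = 0
    multi_morbidity: bool = False
    calibration: Optional[dict[str, Any]] = None

    # -- cross-field validation ------------------------------------------

    @model_validator(mode="after")
    def _validate(self) -> "SimulationConfig":
        errors: list[str] = []
        plan_ids = [p.id for p in self.plans]
        plans = {p.id: p for p in self.plans}
        if len(plan_ids) != len(plans):
            errors.append("plans: duplicate plan ids")

        total = self.uncomplicated_pct + sum(c.incidence_pct for c in self.complications)
        if abs(total - 100.0) > 1e-9:
            errors.append(
                f"uncomplicated_pct + complication incidences must sum to 100, got {total!r}"
            )

        names = [c.name for c in self.complications]
        if len(set(names)) != len(names):
            errors.append("complications: duplicate names")

        for c in self.complications:
            if c.entry_plan not in plans:
                errors.append(f"complications[{c.name}].entry_plan: unknown plan {c.entry_plan!r}")
        if self.uncomplicated_plan not in plans:
            errors.append(f"uncomplicated_plan: unknown plan {self.uncomplicated_plan!r}")

        for p in self.plans:
            if p.successor is not None and p.successor not in plans:
                errors.append(f"plans[{p.id}].successor: unknown plan {p.successor!r}")
            for drug in p.drugs:
                if drug not in self.inventory:
                    errors.append(f"plans[{p.id}].drugs[{drug}]: drug not in inventory")

        # successor chains must be acyclic
        for p in self.plans:
            seen = {p.id}
            cur = p.successor
            while cur is not None and cur in plans:
                if cur in seen:
                    errors.append(f"plans[{p.id}]: successor chain contains a cycle at {cur!r}")
                    break
                seen.add(cur)
                cur = plans[cur].successor

        if sum(s.duration for s in self.schedule) != CYCLES_PER_DAY:
            errors.append(
                f"schedule: shift durations must partition the {CYCLES_PER_DAY}-cycle day"
            )
        starts = sorted(s.start_cycle for s in self.schedule)
        if len(set(starts)) != len(starts):
            errors.append("schedule: duplicate shift start cycles")
        # shifts must tile the day: each shift ends where the next begins (mod 96)
        by_start = sorted(self.schedule, key=lambda s: s.start_cycle)
        for a, b in zip(by_start, by_start[1:] + by_start[:1]):
            if (a.start_cycle + a.duration) % CYCLES_PER_DAY != b.start_cycle:
                errors.append(
                    f"schedule: shift {a.name!r} ends at cycle "
                    f"{(a.start_cycle + a.duration) % CYCLES_PER_DAY}, "
                    f"but {b.name!r} starts at {b.start_cycle}"
                )

        if errors:
            raise ValueError("; ".join(errors))
        return self

    # -- derived lookups --------------------------------------------------

    def plan(self, plan_id: str) -> TreatmentPlan:
        return next(p for p in self.plans if p.id == plan_id)

    def chain_cycles(self, plan_id: str) -> int:
        """Total treated cycles in the successor chain starting at ``plan_id``."""
        total, cur = 0, plan_id
        while cur is not None:
            p = self.plan(cur)
            total += p.duration
            cur = p.successor
        return total

    def shift_at(self, cycle: int) -> Shift:
        """Shift active at absolute cycle index (cycle 0 = midnight day 0)."""
        cod = cycle % CYCLES_PER_DAY
        for s in self.schedule:
            end = s.start_cycle + s.duration
            if end <= CYCLES_PER_DAY:
                if s.start_cycle <= cod < end:
                    return s
            elif cod >= s.start_cycle or cod < end % CYCLES_PER_DAY:
                return s
        raise RuntimeError("schedule does not cover the day")  # unreachable after validation


def loads_config(text: str) -> SimulationConfig:
    """Parse and validate a config from a JSON string."""
    try:
        data = json.loads(text)
    except json.JSONDecodeError as exc:
        raise ConfigError(f"not valid JSON: {exc}") from exc
    try:
        return SimulationConfig.model_validate(data)
    except ValidationError as exc:
        lines = [
            f"{'.'.join(str(x) for x in err['loc'])}: {err['msg']}" for err in exc.errors()
        ]
        raise ConfigError("invalid configuration:\n  " + "\n  ".join(lines)) from exc


def load_config(path: str | Path) -> SimulationConfig:
    """Load and validate a simulation config from a JSON file."""
    return loads_config(Path(path).read_text())


def dump_config(config: SimulationConfig, path: str | Path | None = None) -> str:
    """Serialize a config to canonical (sorted-key) JSON; optionally write it."""
    text = json.dumps(config.model_dump(mode="json"), indent=2, sort_keys=True)
    if path is not None:
        Path(path).write_text(text + "\n")
    return text


def config_hash(config: SimulationConfig) -> str:
    """Stable SHA-256 of the canonical JSON form."""
    return hashlib.sha256(dump_config(config).encode()).hexdigest()


def _jsonify(obj: Any) -> Any:
    """Make numpy scalars/arrays JSON-friendly, recursively."""
    import numpy as np

    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def write_results(results: dict[str, Any], path: str | Path) -> None:
    """Write a results document as canonical, round-trippable JSON."""
    Path(path).write_text(
        json.dumps(_jsonify(results), indent=2, sort_keys=True, allow_nan=False) + "\n"
    )


def read_results(path: str | Path) -> dict[str, Any]:
    return json.loads(Path(path).read_text())


def export_csv(rows: pd.DataFrame | list[dict[str, Any]], path: str | Path) -> None:
    """Export tidy rows (one row per trial per metric/cell) as CSV."""
    df = rows if isinstance(rows, pd.DataFrame) else pd.DataFrame(rows)
    df.to_csv(path, index=False)
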