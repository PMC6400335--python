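"""Closed-form probability arithmetic of the ward model.

Every quantity here is a per-condition *probability of mortality*: the
chance, on (0, 1), that a complication kills the patient over her whole
remaining hospital stay.  The module provides

* composition of several conditions into one composite probability,
* rescaling of a stay-level probability to a single 15-minute cycle,
* the geometric decay of mortality under treatment (efficacy ``eta``),
* the sigmoidal worsening of mortality without treatment (rate ``lam``),
* truncated-normal severity sampling at admission, and
* the analytic calibration of treatment efficacy.

All functions are pure and operate on plain floats; the simulation engine
is the only consumer that carries state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import truncnorm

__all__ = [
    "SeverityDistribution",
    "DeteriorationParams",
    "EfficacyParams",
    "InvalidProbabilityError",
    "composite_mortality",
    "scaled_cycle_mortality",
    "apply_treatment_cycle",
    "treatment_closed_form",
    "apply_deterioration_cycle",
    "deterioration_closed_form",
    "sample_severity",
    "derive_severity_sd",
    "calibrate_efficacy",
]

#: mortality probability that counts as "cured" for calibration purposes
DEFAULT_MORTALITY_FLOOR = 1e-10

#: largest representable probability below 1; deterioration is capped here so
#: the "never reaches 1" invariant survives floating-point rounding
MAX_MORTALITY = float(np.nextafter(1.0, 0.0))

#: fraction of admissions assumed to arrive at or above the severe-maternal-
#: outcome severity (two standard deviations above the mean)
SMO_TAIL_FRACTION = 0.025


class InvalidProbabilityError(ValueError):
    """A value that must be a mortality probability is outside [0, 1)."""


def _check_probability(p: float, name: str = "probability") -> float:
    if not (0.0 <= p < 1.0):
        raise InvalidProbabilityError(f"{name} must lie in [0, 1), got {p!r}")
    return float(p)


@dataclass(frozen=True)
class SeverityDistribution:
    """Truncated-normal severity distribution for one complication.

    The mean is the complication's case fatality rate; the standard
    deviation is pinned by placing the severe-maternal-outcome (SMO)
    mortality two standard deviations above the mean, so that the upper
    2.5% tail of admissions arrives at SMO-level severity.  Samples are
    truncated to the open unit interval.
    """

    mean: float
    sd: float
    smo_mortality: float | None = None
    smo_tail_fraction: float = SMO_TAIL_FRACTION

    def __post_init__(self) -> None:
        _check_probability(self.mean, "severity mean")
        if self.sd <= 0:
            raise ValueError(f"severity sd must be positive, got {self.sd!r}")
        if self.smo_mortality is not None and self.smo_mortality <= self.mean:
            raise ValueError("SMO mortality must exceed the severity mean")

    @classmethod
    def from_smo(cls, mean: float, smo_mortality: float) -> "SeverityDistribution":
        """Build the distribution from (mean, SMO mortality) directly."""
        return cls(
            mean=mean,
            sd=derive_severity_sd(mean, smo_mortality),
            smo_mortality=smo_mortality,
        )


@dataclass(frozen=True)
class DeteriorationParams:
    """Untreated-worsening parameters for one complication.

    ``rate`` is the deterioration rate lambda: *larger* lambda means the
    per-cycle exponent lambda/(lambda+c) is closer to 1, i.e. *slower*
    deterioration.  ``untreated_cycles`` is the consecutive-untreated
    counter c; it resets to zero whenever a treated cycle occurs.
    """

    rate: float
    untreated_cycles: int = 0

    def __post_init__(self) -> None:
        if self.rate <= 0:
            raise ValueError(f"deterioration rate must be positive, got {self.rate!r}")
        if self.untreated_cycles < 0:
            raise ValueError("untreated cycle count cannot be negative")


@dataclass(frozen=True)
class EfficacyParams:
    """Per-cycle treatment efficacy eta; r = 1 - eta is the decay constant.

    ``decay`` may be given explicitly when it is known to more precision
    than 1 - eta can carry (eta very close to 1 loses the low bits of r
    to cancellation); it must then satisfy r = 1 - eta to rounding.
    """

    efficacy: float
    mortality_floor: float = DEFAULT_MORTALITY_FLOOR
    decay: float | None = None

    def __post_init__(self) -> None:
        if not (0.0 <= self.efficacy <= 1.0):
            raise ValueError(f"efficacy must lie in [0, 1], got {self.efficacy!r}")
        if self.decay is not None and abs((1.0 - self.efficacy) - self.decay) > 1e-9:
            raise ValueError("decay must equal 1 - efficacy")

    @property
    def decay_constant(self) -> float:
        return 1.0 - self.efficacy if self.decay is None else self.decay


def composite_mortality(per_condition: list[float]) -> float:
    """Combine per-condition mortality probabilities into one.

    Conditions are assumed to threaten the patient independently, so the
    survival probabilities multiply: ``p_c = 1 - prod(1 - p_k)``.  An
    empty list (no complication) gives 0.
    """
    acc = 1.0
    for p in per_condition:
        _check_probability(p, "per-condition mortality")
        acc *= 1.0 - p
    return 1.0 - acc


def scaled_cycle_mortality(p_c: float, n_remaining: int) -> float:
    """Per-cycle death probability consistent with a stay-level probability.

    ``p_c`` is the chance of dying at any point in the remaining
    ``n_remaining`` cycles; the per-cycle probability p solves
    ``(1 - p)**n = 1 - p_c``.
    """
    _check_probability(p_c, "composite mortality")
    if n_remaining < 1:
        raise ValueError(f"n_remaining must be >= 1, got {n_remaining!r}")
    if p_c == 0.0:
        return 0.0
    # -expm1(log1p(-p_c)/n) is exact for p_c near 0 and near 1
    return -math.expm1(math.log1p(-p_c) / n_remaining)


def apply_treatment_cycle(p: float, eff: EfficacyParams) -> float:
    """One treated cycle: p -> p * (1 - eta)."""
    _check_probability(p)
    return p * eff.decay_constant


def treatment_closed_form(p0: float, eff: EfficacyParams, c: int) -> float:
    """Mortality after ``c`` consecutive treated cycles: p0 * r**c."""
    _check_probability(p0)
    if c < 0:
        raise ValueError("cycle count must be non-negative")
    return p0 * eff.decay_constant**c


def apply_deterioration_cycle(p: float, det: DeteriorationParams) -> float:
    """One untreated cycle: p -> p ** (lambda / (lambda + c)).

    ``det.untreated_cycles`` must already count the current untreated
    cycle (c >= 1).  Since the exponent is below 1 and p < 1, the update
    strictly worsens the condition while staying below 1.  p == 0 means
    no condition and is passed through unchanged.
    """
    _check_probability(p)
    if p == 0.0:
        return 0.0
    c = det.untreated_cycles
    if c < 1:
        raise ValueError("current untreated cycle count must be >= 1")
    return min(p ** (det.rate / (det.rate + c)), MAX_MORTALITY)


def deterioration_exponent(rate: float, c: int) -> float:
    """Exponent lambda**c * Gamma(lambda+1) / Gamma(lambda+c+1).

    Equals prod_{k=1..c} lambda/(lambda+k); computed in log space so
    large c or lambda cannot overflow.
    """
    if rate <= 0:
        raise ValueError("deterioration rate must be positive")
    if c < 0:
        raise ValueError("cycle count must be non-negative")
    if c == 0:
        return 1.0
    return math.exp(c * math.log(rate) + gammaln(rate + 1.0) - gammaln(rate + c + 1.0))


def deterioration_closed_form(p0: float, rate: float, c: int) -> float:
    """Mortality after ``c`` consecutive untreated cycles.

    Closed form of the per-cycle update: the exponents lambda/(lambda+k)
    for k = 1..c multiply to lambda**c Gamma(lambda+1)/Gamma(lambda+c+1),
    so ``p(c) = p0 ** (lambda**c Gamma(lambda+1)/Gamma(lambda+c+1))`` —
    a sigmoidal rise toward (but never reaching) 1.
    """
    _check_probability(p0)
    if p0 == 0.0:
        return 0.0
    if c == 0:
        return p0
    return min(p0 ** deterioration_exponent(rate, c), MAX_MORTALITY)


def sample_severity(dist: SeverityDistribution, rng: np.random.Generator) -> float:
    """Draw one admission severity from the truncated normal on (0, 1).

    Sampling is by inverse CDF on the truncated quantile range, so it is
    exact, rejection-free and reproducible under seeding.
    """
    a = (0.0 - dist.mean) / dist.sd
    b = (1.0 - dist.mean) / dist.sd
    u = rng.random()
    x = float(truncnorm.ppf(u, a, b, loc=dist.mean, scale=dist.sd))
    # ppf can return the boundary for u at the extremes of float resolution
    return min(max(x, np.nextafter(0.0, 1.0)), np.nextafter(1.0, 0.0))


def derive_severity_sd(mean: float, smo_mortality: float) -> float:
    """Standard deviation placing SMO mortality two SDs above the mean."""
    _check_probability(mean, "severity mean")
    if smo_mortality <= mean:
        raise ValueError(
            "SMO mortality must exceed the mean severity "
            f"(got mean={mean!r}, smo={smo_mortality!r})"
        )
    return (smo_mortality - mean) / 2.0


def calibrate_efficacy(
    mean_severity: float,
    duration_cycles: int,
    floor: float = DEFAULT_MORTALITY_FLOOR,
) -> EfficacyParams:
    """Solve for the per-cycle efficacy that cures the mean case on time.

    Chooses eta so that geometric decay over ``duration_cycles`` treated
    cycles takes the mean severity down to ``floor``:
    ``eta = 1 - (floor / mean) ** (1 / duration)``.
    """
    _check_probability(mean_severity, "mean severity")
    if duration_cycles < 1:
        raise ValueError("duration must be at least one cycle")
    if not (0.0 < floor < mean_severity):
        raise ValueError("mortality floor must lie strictly between 0 and the mean severity")
    r = (floor / mean_severity) ** (1.0 / duration_cycles)
    return EfficacyParams(efficacy=1.0 - r, mortality_floor=floor, decay=r)
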