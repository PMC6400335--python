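"""Show how a patient's mortality probability evolves cycle by cycle.

A condition's probability of mortality p lives on (0,1) and covers the
whole remaining stay.  Treated cycles shrink it geometrically with the
plan efficacy eta (p -> p(1-eta)); untreated cycles grow it as
p -> p^(lambda/(lambda+c)), a sigmoidal climb toward 1 whose speed is
set by the deterioration rate lambda and the consecutive-untreated
counter c.
"""

from wardsim import (
    DeteriorationParams,
    EfficacyParams,
    apply_deterioration_cycle,
    apply_treatment_cycle,
    deterioration_closed_form,
    scaled_cycle_mortality,
    treatment_closed_form,
)

p0, eta, lam = 0.40, 0.15, 25.0

print(f"start: p = {p0}, efficacy eta = {eta}, deterioration rate lambda = {lam}")
print("\nuntreated (counter c runs 1, 2, ...):")
p = p0
for c in range(1, 9):
    p = apply_deterioration_cycle(p, DeteriorationParams(rate=lam, untreated_cycles=c))
    print(f"  after {c} untreated cycles: p = {p:.4f}")
print(f"  closed form at c=8:        p = {deterioration_closed_form(p0, lam, 8):.4f}")

print("\ntreated from there (geometric decay):")
eff = EfficacyParams(eta)
q = p
for k in range(1, 9):
    q = apply_treatment_cycle(q, eff)
print(f"  after 8 treated cycles:    p = {q:.4f}")
print(f"  closed form:               p = {treatment_closed_form(p, eff, 8):.4f}")

print("\nper-cycle death probability when p covers a 48-cycle remaining stay:")
print(f"  p_cycle = {scaled_cycle_mortality(p, 48):.5f}")
# The two closed forms match their iterated updates exactly; the scaled
# probability is what the survival draw uses each cycle so that the
# stay-level risk comes out right.
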