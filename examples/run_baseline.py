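"""Run the baseline ward for one simulated month and summarize outcomes.

The baseline emulates a busy referral maternity ward: three shifts
(morning 5 nurses/3 doctors, evening 3/2, night 3/1), per-15-minute
admission probabilities of 0.4 / 0.28 / 0.625, five potentially
life-threatening complications on 13.05% of admissions, and monthly
restocking of oxytocin (200 packs) and hydralazine (11 packs).
"""

from wardsim import default_mmh_config, run_trials, summarize

config = default_mmh_config(horizon_days=30, n_trials=5)
trials = run_trials(config)
stats = summarize(trials)

print(f"trials:               {stats.n_trials} x 30 days")
print(f"admissions per month: {stats.admissions_per_month:.0f}")
print(f"mean daily census:    {stats.mean_daily_census:.1f} "
      f"(sd {stats.sd_daily_census:.1f})")
print(f"maternal deaths:      {stats.deaths_mean:.1f} per month "
      f"(sd {stats.deaths_sd:.1f})")
print(f"mortality rate among complicated patients: "
      f"{stats.mortality_rate_complicated_pct:.2f}%")
print("case fatality rates (%):")
for name, cfr in sorted(stats.cfr_pct.items()):
    inc = stats.incidence_pct[name]
    print(f"  {name:<22} CFR {cfr:5.2f}   incidence {inc:5.2f}")

# The census and mortality-rate figures describe how loaded the ward is
# and how dangerous a complication is under current resources; the CFRs
# are per-complication and move when staffing or drug supply changes.
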