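"""Ask how oxytocin supply and restocking frequency change maternal deaths.

Varies the initial oxytocin stock with and without monthly restocking
while pinning hydralazine at 11 packs (no restock), mirroring how a
supply-policy question would be posed: every cell reuses the same trial
seeds, so differences between cells are due to the supply policy, not to
different random patient streams.
"""

from wardsim import SweepSpec, default_mmh_config, sweep_medication

config = default_mmh_config()
spec = SweepSpec(base_config=config, n_trials=3, base_seed=11,
                 horizon_cycles=42 * 96)  # six weeks, scaled down for a demo

table = sweep_medication(spec, drug="oxytocin", stock_levels=(50.0, 100.0, 200.0))
cells = (table.groupby(["stock", "restock"])["deaths"]
         .agg(["mean", "std"]).reset_index())
print(cells.to_string(index=False))

worst = cells.loc[cells["mean"].idxmax()]
best = cells.loc[cells["mean"].idxmin()]
print(f"\nworst cell: {worst['stock']:.0f} packs, restock={bool(worst['restock'])}"
      f" -> {worst['mean']:.1f} mean deaths")
print(f"best cell:  {best['stock']:.0f} packs, restock={bool(best['restock'])}"
      f" -> {best['mean']:.1f} mean deaths")
# Mean deaths per cell over the common seeds; the gap between the
# stocked-and-restocked cells and the stockout cells is the mortality
# cost attributable to the oxytocin supply chain.
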