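"""Harvest records into yield components.

Fruits under 3 g are counted as aborted and excluded from yield; fresh
yield is scaled to kg per m2 of ground via the planting density
(2 stems / (1.5 m x 0.3 m) = 4.44 stems/m2); dry yield applies the fruit
dry-matter content.
"""

from cucurgrow import (
    dry_yield,
    filter_aborted,
    generate_climate,
    generate_trial,
    packaged_scenarios,
    planting_density,
    yield_summary,
)

density = planting_density(1.5, 0.3, 2)
print("planting density: %.2f stems/m2" % density)

climate = generate_climate(seed=42)
scen = packaged_scenarios()["josho"]
trial = generate_trial(scen, climate)
kept, aborted = filter_aborted(trial.harvest_cohort_events())
ys = yield_summary(kept, aborted, density, stems_per_plant=2, trial_end_dat=228)

print(f"josho: fresh yield {ys.fresh_yield_kg_m2:.1f} kg/m2, "
      f"{ys.fruit_number_m2:.0f} fruits/m2, "
      f"mean fruit weight {ys.mean_fruit_fw_g:.0f} g")
print(f"       abortion ratio {ys.abortion_ratio:.1%} "
      f"({ys.n_aborted} of {ys.n_kept + ys.n_aborted} fruits)")
print(f"       dry yield {dry_yield(ys.fresh_yield_kg_m2, scen.fruit_dmc):.2f} kg/m2 "
      f"at {scen.fruit_dmc:.3f} g/g DM content")
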