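"""Generate one synthetic greenhouse trial and look at its raw tables.

The 'josho' scenario emulates a vigorous cucumber cultivar in a 228-day
October-transplanted glasshouse trial: daily climate, weekly node counts
on six plants, weekly leaf dimensions on three plants, destructive dry
weights at six dates, and daily harvest records on nine plants.
"""

from cucurgrow import generate_climate, generate_trial, packaged_scenarios

climate = generate_climate(seed=42)
scenario = packaged_scenarios()["josho"]
trial = generate_trial(scenario, climate)

print("climate days:", len(trial.climate))
print("temperature range (degC): %.1f-%.1f"
      % (trial.climate.t_mean.min(), trial.climate.t_mean.max()))
print("\nnode observations (head):")
print(trial.node_obs.head(3).to_string(index=False))
print("\nharvest events:", len(trial.harvest_events),
      "| destructive records:", len(trial.destructive_obs))
print("\nThe node table counts nodes per stem weekly from 38 DAT; the")
print("harvest table lists every fruit picked (aborted ones are < 3 g).")
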