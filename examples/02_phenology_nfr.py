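"""Thermal time and the node formation rate (NFR).

Node counts are baseline-subtracted at 38 DAT and regressed against
accumulated daily mean temperature from the same date; the per-plant
final slope, averaged over plants, is the cultivar's NFR in nodes per
accumulated degC day.
"""

from cucurgrow import (
    accumulate_thermal_time,
    estimate_nfr,
    generate_climate,
    generate_trial,
    node_increase,
    packaged_scenarios,
)

climate = generate_climate(seed=42)
scens = packaged_scenarios()
for name in ("josho", "yusho"):
    trial = generate_trial(scens[name], climate)
    thermal = accumulate_thermal_time(climate, start_dat=38)
    curve = node_increase(trial.node_obs, thermal, start_dat=38)
    est = estimate_nfr(curve)
    print(f"{name:7s} NFR = {est.estimate:.4f} "
          f"(95% CI {est.ci_low:.4f}-{est.ci_high:.4f}) nodes per degC day, "
          f"n = {est.n_plants} plants  [truth {scens[name].nfr_true}]")
print("\nA vigorous cultivar (~0.022) adds roughly one node every ~45 degC day;")
print("the slower cultivars (~0.015) need ~65 degC day per node.")
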