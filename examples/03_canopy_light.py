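"""Leaf-area allometry, daily LAI and Beer-Lambert light interception.

Leaf area comes from width x length allometry; per-stem areas build the
daily LAI series (interpolated between weekly measurements); intercepted
PAR is SR x T x 0.5 x (1 - exp(-k LAI)) with T = 0.51 and k = 0.9.
"""

import numpy as np

from cucurgrow import (
    build_lai,
    daily_interception,
    estimate_k,
    generate_climate,
    generate_trial,
    leaf_area,
    packaged_scenarios,
)

print("single leaf 10 x 15 cm -> %.1f cm2" % leaf_area(10, 15))

climate = generate_climate(seed=42)
trial = generate_trial(packaged_scenarios()["josho"], climate)
lai = build_lai(trial.leaf_obs, density=trial.meta["density_stems_m2"],
                trial_length=len(climate))
il = daily_interception(climate, lai)
print("LAI plateau: %.2f m2/m2" % lai["lai"].max())
print("cumulative intercepted PAR over the trial: %.0f MJ/m2"
      % il["cum_il"].iloc[-1])

# extinction coefficient from paired above/below-canopy PAR readings
rng = np.random.default_rng(0)
lai_pairs = rng.uniform(0.8, 3.0, 15)
above = rng.uniform(200, 600, 15)
below = above * np.exp(-0.9 * lai_pairs * np.exp(rng.normal(0, 0.02, 15)))
print("k recovered from 15 noisy PAR pairs: %.3f (true 0.9)"
      % estimate_k(above, below, lai_pairs))
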