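"""Recover a distance-dependent travel-speed law from a simulated travel log.

Volunteers closer to the patient tend to walk; farther ones cycle or drive,
so speed grows roughly linearly with distance.  The fitting procedure bins
distances into 100-m blocks, takes the median speed per block (robust to
outliers), drops the unreliable 0-100 m block and zero travel times, and
regresses block-median speed on block midpoint.
"""

import numpy as np

from cfrsim import fit_speed_model, travel_time_min

rng = np.random.default_rng(42)

# simulate 5,000 noisy responder trips under a known speed law
true_intercept, true_slope = 1.83, 0.0108  # km/h, km/h per metre
d = rng.uniform(0.0, 1200.0, 5000)
speed = np.clip(true_intercept + true_slope * d + rng.normal(0, 0.8, d.size), 0.3, None)
t = 3.6 * d / speed  # seconds

fit = fit_speed_model(d, t)
m = fit.model
print(f"true law:   speed = {true_intercept} + {true_slope} * distance_m  (km/h)")
print(f"fitted law: speed = {m.intercept_kmh:.3f} + {m.slope_kmh_per_m:.5f} * distance_m")
print(f"R^2 on block medians: {fit.r_squared:.3f}  ({fit.block_midpoint_m.size} blocks)")
print(f"implied travel time at 1 km: {travel_time_min(1000.0, m):.2f} min "
      f"(default model: {travel_time_min(1000.0):.2f} min)")
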