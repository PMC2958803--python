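"""Correlation time controls population spread in a 30-cm tank.

Runs 30-minute simulations of 1000 agents replaying library trajectories
at several correlation times tau and prints the population-position SD
after 30 min and its growth rate.  Short tau gives a tight, slowly
spreading cohort; minute-scale tau disperses the population through the
whole water column within the half-hour.
"""

from planktonwalk import (SimConfig, VelocityModelParams, generate_library,
                          run, sd_growth_slope, sd_over_time, stage_rng)

library = generate_library(VelocityModelParams(), 1032, stage_rng(42, "library"))

print("tau [s]   SD(30 min) [cm]   SD growth [mm/min]")
for tau in (0.25, 1.0, 100.0, 500.0, 1800.0):
    cfg = SimConfig(tau=tau, duration=1800.0, n_agents=1000,
                    column_height_cm=30.0, n_replicates=3, seed=42)
    series = sd_over_time(run(cfg, library))
    slope = sd_growth_slope(series, window="growth")
    print(f"{tau:7.2f}   {series.mean_sd[-1]:12.2f}      {slope:10.2f}")

print("\nThe mean upward drift is identical for every tau; only the spread "
      "changes.  The jump between tau = 1 s and tau = 100 s is the "
      "ballistic-to-diffusive transition moving past the 30-min observation "
      "window.")
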