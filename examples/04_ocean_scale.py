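"""Scaling up: dispersal and prey-layer encounter in a 15-m water column.

Expands the tank model to a 15-m column over 12-24 h.  Prints (a) the
vertical extent occupied by the population after 12 h at three
correlation times, and (b) how much earlier a strongly correlated
population reaches a 1-m-thick phytoplankton layer 4 m above the release
point, and how much longer its first-arriving quartile keeps a presence
there, relative to uncorrelated walkers.

This is the slow example (~2 min): it simulates 4000+ agent-hours at 4 Hz.
"""

from planktonwalk import (LayerSpec, SimConfig, VelocityModelParams,
                          generate_library, layer_encounter,
                          mean_vertical_range, relative_encounter, run,
                          stage_rng)

library = generate_library(VelocityModelParams(), 1032, stage_rng(42, "library"))

print("occupied vertical extent (central 95%) after 12 h:")
for tau in (1.0, 300.0, 900.0):
    cfg = SimConfig(tau=tau, duration=43_200.0, n_agents=1000,
                    column_height_cm=1500.0, n_replicates=3, seed=42,
                    output_interval=300.0)
    extent = mean_vertical_range(run(cfg, library), 43_200.0)
    print(f"  tau = {tau:6.0f} s: {extent / 100:6.2f} m")

layer = LayerSpec(bottom_m=4.0, thickness_m=1.0)
enc = {}
for tau in (0.25, 1800.0):
    cfg = SimConfig(tau=tau, duration=86_400.0, n_agents=1000,
                    column_height_cm=1500.0, n_replicates=3, seed=42,
                    output_interval=60.0)
    enc[tau] = layer_encounter(run(cfg, library), layer, fraction=0.25)

for tau, e in enc.items():
    print(f"tau = {tau:6g} s: 25% of population in layer at "
          f"{e.arrival_time_s / 3600:5.2f} h; cohort present for "
          f"{e.residence_s / 3600:5.2f} h")
advance, excess = relative_encounter(enc[1800.0], enc[0.25])
print(f"\ncorrelated walkers arrive {advance:.1f} h earlier and maintain a "
      f"presence {excess:.1f} h longer than uncorrelated walkers --\n"
      "persistent individual motion is a population-level foraging advantage.")
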