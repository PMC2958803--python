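# planktonwalk

Individual-based correlated random walk (CRW) models that link the
swimming behavior of single planktonic cells to the dispersal of whole
populations — and, in reverse, use observed population distributions to
infer how persistent individual motion must be.

## The problem

A heterotrophic dinoflagellate like *Oxyrrhis marina* swims a few
hundred µm/s along helical paths, and video tracking yields thousands of
short (3–33 s) 3-D trajectories.  Population surveys, meanwhile, count
organisms at fixed depths over hours.  The bridge between the two scales
is the **velocity correlation time τ**: how long an individual keeps
"doing what it was doing".  Velocity autocorrelation within 30-s tracks
never decays, so τ cannot be read off the tracks directly — but it can
be inferred by simulating populations of virtual swimmers across a range
of τ and asking which one reproduces the observed vertical abundance
profiles.  The answer matters ecologically: persistent (large-τ) walkers
disperse an order of magnitude faster and reach remote prey layers hours
earlier than uncorrelated walkers with identical speeds.

## The model

Each of *N* agents carries a vertical position `x_i(t)`, a vertical
velocity `w_i(t)`, and a currently assigned swimming trajectory `T_j`
drawn from a library of recorded (here: synthetically generated) tracks.
Per 0.25-s time step (the 4-Hz video rate):

    x_i(t + Δt) = x_i(t) + w_i(t) Δt

with `w_i` replayed in sequence from `T_j`, and a fresh trajectory
assigned with probability

    P(reassign) = Δt / τ .

The hidden state (the assigned trajectory) switches as a Markov chain;
the emitted velocities inherit the within-track structure.  `τ = Δt`
gives an uncorrelated biased walk; `τ → ∞` gives ballistic motion at
each cell's own mean velocity.  Agents hitting the column boundaries are
reassigned tracks with net displacement back into the column.  Because
no raw tracks are deposited, `planktonwalk.synth` generates libraries
calibrated to the published statistics: pooled vertical velocity median
118 µm/s, SD 110 µm/s, negative skew (a few strong down-swimmers), mean
speed 235 ± 103 µm/s, 1-s helical periodicity, durations 3–33 s with
median 5.2 s, and explicit cell-to-cell heterogeneity (`between_frac`,
the between-path share of the velocity variance).

See `docs/methods.md` for the full model description, calibration
choices and limitations.

## Worked example

```python
import numpy as np
from planktonwalk import (SimConfig, VelocityModelParams, generate_library,
                          run, sd_growth_slope, sd_over_time, stage_rng)

library = generate_library(VelocityModelParams(), 1032, stage_rng(42, "library"))
for tau in (0.25, 1.0, 100.0, 500.0, 1800.0):
    cfg = SimConfig(tau=tau, duration=1800.0, n_agents=1000,
                    column_height_cm=30.0, n_replicates=3, seed=42)
    series = sd_over_time(run(cfg, library))
    print(tau, round(series.mean_sd[-1], 2),
          round(sd_growth_slope(series, window="growth"), 2))
```

prints (SD of the vertical population distribution after 30 min in a
30-cm tank, and its growth rate):

```
tau [s]   SD(30 min) [cm]   SD growth [mm/min]
   0.25           0.30            0.05
   1.00           0.54            0.13
 100.00           4.27            1.39
 500.00           6.84            2.75
1800.00           7.87            3.35
```

Second-scale correlation keeps the population in a tight cohort
(≈ 0.5 cm spread, as observed for uncorrelated models); minute-scale
correlation disperses it through the whole column within the half hour —
a >20-fold difference in spread at identical mean drift.  The
`examples/` scripts walk through each capability: library generation,
tank dispersal, RMSE model selection (which τ explains an observed
profile), and ocean-scale prey-layer encounter; `planktonwalk --help`
exposes the same stages as a CLI (`generate`, `simulate`, `observe`,
`compare`, `metrics`, `pipeline`).

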