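# Methods

`planktonwalk` links individual swimming behavior of a planktonic
protist (a heterotrophic dinoflagellate of the *Oxyrrhis marina* type)
to vertical population dispersal, through an individual-based,
hidden-Markov correlated random walk (CRW).  This note documents the
model, the synthetic-data generator that stands in for laboratory video
tracks, the numerical choices, and what the tests do and do not show.

## The correlated random walk

Each of `n_agents` model organisms carries a vertical position `z` (cm),
a reference to one library trajectory `T_j`, and a step index within it.
Per time step `dt` (default 0.25 s, the 4-Hz video rate):

1. with probability `dt / tau` the agent is assigned a fresh,
   uniformly drawn trajectory and restarts at its first recorded
   vertical velocity; otherwise it advances one sample within its
   current trajectory, replaying the recorded velocities in order;
2. the position updates as `z(t + dt) = z(t) + w(t) dt`.

`tau` is the velocity correlation time: the velocity autocorrelation of
this jump-renewal process decays as `exp(-t/tau)`, so motion is
ballistic for `t << tau` and diffusive for `t >> tau`.  `tau = dt`
realizes the uncorrelated walk (a fresh draw every step); an effective
"tau = 0" is therefore represented by `tau = dt`, since `dt/tau` is
undefined at zero.  The model is one-dimensional because the quantity of
interest is vertical redistribution and there are no horizontal
gradients.

**Trajectory exhaustion.** Correlation times (up to 1800 s) far exceed
track durations (3–33 s), and no recorded rule covers an exhausted
track.  Default: cyclic replay (`replay_mode="wrap"`) — the agent loops
its track until a reassignment fires, preserving the *cell's* identity
and hence cell-to-cell heterogeneity at long `tau`.  The alternative
(`"redraw"`, a fresh uniform draw on exhaustion) caps the effective
correlation time at the ~5-s track scale, which erases every
`tau`-dependence beyond ~30 s; since `tau`-dependence out to 1800 s is
the phenomenon of interest, wrap is the only viable default, and the
rule is isolated behind one switch so both can be tested.

**Boundaries.** In a bounded column an agent crossing the surface is
clamped to it and reassigned a uniformly drawn track with net *downward*
displacement; at the bottom, net upward.  Libraries lacking either sign
are rejected at simulation start.  Reflection is not used: the organisms
steer, they do not bounce.

**Initial condition.** Organisms are released at the base of the
column; the default is a uniform bottom slab of 0.5 cm.  The slab height
is pinned by the short-correlation limit: an uncorrelated 30-min tank
run has diffusive spread ≈ 0.23 cm and a reported total SD ≈ 0.5 cm, so
the release spread must be a few millimetres; with a 0.5-cm slab the
simulated `tau <= 1 s` SD reproduces ≈ 0.5 cm.

**Randomness.** One top-level integer seed feeds a documented
`SeedSequence` tree (`spawn_key = (stage, index)`), so the library
generator, each simulation replicate, and the virtual sampler own
independent, individually reproducible streams.  Within one replicate
the engine draws fixed-order per-step arrays (reassignment uniforms,
candidate track indices, boundary redraws); a naive per-agent reference
implementation consumes the identical stream and must agree bit for
bit, which the suite asserts.  Changing `n_agents` reshuffles draws — a
deliberate trade against per-agent streams, which would have made the
vectorized/naive equivalence check far weaker.

## The synthetic trajectory generator

No deposited tracks exist, so the generator emulates the published
summary statistics and serves as the simulator's input library
(~1032 tracks, 4 Hz):

- **Durations**: truncated log-normal on [3, 33] s; `sigma_ln = 0.556`
  puts ~12% of mass above 10 s (matching the reported 124/1032), and the
  base median is solved numerically so the truncated median is 5.2 s.
- **Path-mean vertical velocity** `w_j`: skew-normal with fixed shape
  `alpha = -2` (clearly negative skew without a degenerate half-normal
  tail), SD `sqrt(between_frac) * pop_sd_w`, and median
  `pop_median_w + 2 µm/s`.  The +2 µm/s offset compensates the median
  shift from convolving a negatively skewed between-path distribution
  with symmetric within-path variability, so the *pooled* sample — the
  statistic the laboratory actually reports — has median ≈ 118 µm/s.
- **Within-path fluctuation**: a helical oscillation (period 1 s,
  amplitude 20% of path speed, in the plane normal to the mean heading)
  plus AR(1) noise with a 5-s correlation time, together carrying
  `(1 - between_frac) * pop_sd_w²` of vertical-velocity variance.  Both
  are **exactly demeaned over the track**, so the realized track-mean
  velocity equals the drawn `w_j`.  This makes the between/within
  variance decomposition exact and, more importantly, makes
  `between_frac` the real long-horizon dispersal knob: under cyclic
  replay an agent's time-averaged velocity is its track mean, so
  whatever variance leaks into track means drives dispersal at long
  `tau`.  Without demeaning, slow noise on 3–33-s tracks pushes nearly
  the full pooled SD into the track means and `between_frac` does
  nothing.
- **Speed and heading**: track-mean speed from a truncated normal
  (235 ± 103 µm/s on [50, 600] µm/s, and at least `1.05 |w_j|`); the
  heading follows from `cos(angle) = w_j / speed`, so downward tracks
  get angles beyond 90°.  The printed direction statistics (57 ± 34° off
  vertical) are treated as an emergent consistency check, not an input —
  speed, vertical velocity and angle cannot all be prescribed
  independently.

`between_frac` (default 0.5) splits the pooled vertical-velocity
variance between cell-to-cell heterogeneity and within-track
fluctuation.  The split is unreported in the source data and was
calibrated once against the dispersal family (the 30-min tank SD curves
across `tau`) with the pre-build closed-form and brute-force oracles,
then frozen; all downstream results inherit this calibration, which is
why magnitude checks carry generous (±50%) bands.

### What the generator does and does not emulate

It reproduces pooled vertical-velocity median/SD/skew, track-duration
statistics, speed scale, helical periodicity, strong within-track
velocity persistence, and cell-to-cell heterogeneity.  It does **not**
reproduce the empirical histogram bin-by-bin, duration–velocity
correlations (durations are drawn independently of speed, though in the
laboratory faster cells likely left the camera volume sooner), diel or
hunger-state behavior shifts, or any horizontal structure.  Tests
passing on synthetic libraries show the *pipeline* is correct under
these study conditions; they do not validate the behavioral model
against new organisms.

## Trajectory statistics

Tracks are smoothed with cubic smoothing splines (per coordinate;
residual budget `smoothing_level · n · var(coordinate)`, so 0
interpolates).  The smoothing level applied in the laboratory is
unreported; it is config-exposed, and a spectral test verifies that
moderate smoothing removes ≥90% of Nyquist-frequency jitter without
touching linear motion.  Velocities are forward differences on the
grid (the differencing scheme is likewise unreported; forward
differences make position reconstruction exact).

Velocity autocorrelation is computed per track with the mean
subtracted and normalized by the lag-0 variance; the default estimator
divides by `n` (biased) for stability on short tracks, with an
unbiased (`n - lag`) option, and lags run to half the track length.
Note a structural limit: with the mean subtracted, the biased sample
ACF cannot stay high out to half the record — it is bounded by
`(n-l)/n` and its lags sum to −1/2 — so "no observable de-correlation"
is verified at short lags (after filtering the 1-s helix period with an
exact one-period moving average) and through the superlinear growth of
net distance versus a `sqrt(t)` diffusive reference, not as a uniform
ACF threshold across all lags.

Sample skewness is the adjusted Fisher–Pearson `G1` (scipy,
bias-corrected).

## Virtual observation and model–data comparison

The virtual cameras copy the laboratory design: six horizons ~5 cm
apart, each filmed 2 min per pass, passes every 25 min (design range
20–30 min), first pass 15 min after release, horizon order randomized
once per experiment.  The 9-ml stereo volume inside a 1.3-cm-tall field
of view maps to a full-width 1.3-cm slab with volumetric subsampling
factor `9 / (1000 · 1.3/30)` ml/ml, converting agents-in-slab to
organisms per observation.  Counts are expected values by default
(segment-averaged over ~1800 frames, the reported SEs are small); a
Poisson mode models frame-count noise when integer counts are wanted.
Counts, not proportions, enter the comparison (profiles share a total
population; the choice is recorded in the profile metadata).

Model selection: RMSE over all horizon × pass cells between predicted
and observed profiles sampled on the identical schedule; raw replicate
RMSEs are scaled by the global maximum *before* averaging (so the scaled
maximum is exactly 1); one one-way ANOVA across all candidate `tau`
values with Bonferroni-corrected pairwise t-tests at alpha = 0.05.  On
synthetic data generated at `tau* = 900 s`, scaled RMSE falls
monotonically up to `tau*`, every pair among `tau >= 500 s` is
indistinguishable under the Bonferroni-corrected post-hoc, and the
minimizer recovers `tau*` within a factor of 3 — the comparison pins a
lower bound on the correlation time, not an upper one.

## Dispersal and encounter metrics

- **Spread**: within-replicate population SD (population convention,
  divide by `n`; two agents at `z`, `z+d` give `d/2`), averaged over
  replicates.  Growth rates in mm/min come from a least-squares fit;
  the default acceptance fit uses the *growth window* — from release
  until the SD series first reaches 95% of its maximum — because in a
  30-cm tank the SD saturates once the population fills the column and
  a full-window fit measures the saturation plateau, not the dispersal
  rate the printed mm-per-minute figures describe.
- **Vertical extent**: central-95% span (2.5th–97.5th percentiles).
  With ~1000 agents a min–max range is dominated by the single most
  extreme cell; the central-95% convention is stable and is the one
  under which the printed 10 cm / 2.5 m / 4 m extents are reproduced.
  `minmax` is selectable.
- **Farthest quartile**: mean |net displacement| of the top 25% of
  agents, unbounded column only.
- **Prey layer** (1-m layer in a 15-m column, bottom 4 m above the
  release by default; both config-exposed since the original placement
  is unreported): arrival is the earliest time 25% of the population
  has entered the layer.  Residence of that first-arriving cohort is,
  by default, the **presence window** — first entry to last exit of
  any cohort member.  The per-agent total-occupancy alternative is
  implemented (`residence_mode="occupancy"`) but is nearly invariant
  in `tau`: a population advecting through a thin layer at mean drift
  `v` has expected per-agent occupancy ≈ thickness/`v` regardless of
  correlation (measured difference ≈ 0.02 h between `tau = 1800 s` and
  uncorrelated walkers).  Only a cohort-level window reproduces the
  hours-scale residence contrast, because long correlation staggers
  arrivals and re-entries across hours while uncorrelated walkers
  transit as one tight pulse.

## Problem sizes and numerical notes

Default experiments are 1000 agents × triplicate at 4 Hz: 30-min tank
runs (7,200 steps), 12-h ocean runs (172,800 steps) and 24-h prey-layer
runs (345,600 steps); the full acceptance script is a few minutes on one
core.  Positions are stored in cm, velocities in µm/s, with the single
conversion constant in `planktonwalk._units`.  Output snapshots default
to 30 s (tank) / 60–300 s (ocean); layer statistics read snapshots, and
at ≤600 µm/s an agent moves ≤3.6 cm per 60-s snapshot — far below the
1-m layer thickness, so no crossing is missed.  Degenerate inputs
(zero-variance ACF, all-zero RMSE scaling, identical ANOVA groups,
missing boundary-sign tracks) raise typed errors rather than returning
silent zeros.

## Known limitations

- The between/within variance split and the release-slab height are
  calibration constants, not measurements; conclusions that depend
  finely on either should be re-derived from real tracks.
- Hydrodynamics (turbulence, shear, eddy diffusivity), behavioral
  responses to prey, aggregation, and demographic change are out of
  scope; dispersal here is behavior-only.
- The residence definition is an operationalization of an underspecified
  quantity; both modes are reported by the API so the choice is visible.
- Replay wraps short tracks cyclically; at `tau >> 33 s` an agent's
  velocity effectively *is* its track mean plus a periodic residual,
  which is the intended heterogeneity-preserving behavior but is an
  assumption, not an observation.
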