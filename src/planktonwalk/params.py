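"""Configuration types for the generator, simulator, virtual camera and
prey-layer analyses.

All parameters carry explicit units in their names or docstrings.
Validation happens at construction; a :class:`ConfigurationError` names
the offending field.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields


class ConfigurationError(ValueError):
    """Raised when a parameter value is out of range or inconsistent."""


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ConfigurationError(msg)


@dataclass(frozen=True)
class VelocityModelParams:
    """Population model for *Oxyrrhis marina*-like vertical swimming.

    The vertical-velocity population is a negatively skewed (skew-normal)
    distribution of per-path mean velocities plus within-path fluctuation;
    ``between_frac`` splits the pooled variance ``pop_sd_w**2`` between the
    two levels.  Defaults reproduce the laboratory summary statistics:
    pooled median 118 µm/s, pooled SD 110 µm/s, negative skew, mean speed
    235 ± 103 µm/s, mean direction 57 ± 34° off vertical, track durations
    3–33 s with median 5.2 s at 4 Hz.
    """

    pop_median_w: float = 118.0      # µm/s, pooled vertical-velocity median
    pop_sd_w: float = 110.0          # µm/s, pooled vertical-velocity SD
    skew_sign: str = "negative"
    between_frac: float = 0.5        # share of pooled variance between paths
    mean_speed: float = 235.0        # µm/s
    sd_speed: float = 103.0          # µm/s
    mean_angle_deg: float = 57.0     # degrees off vertical
    sd_angle_deg: float = 34.0
    helix_period_s: float = 1.0
    helix_amplitude_frac: float = 0.2   # fraction of path speed
    duration_median_s: float = 5.2
    duration_min_s: float = 3.0
    duration_max_s: float = 33.0
    sample_hz: float = 4.0
    # calibration constants (see docs/methods.md)
    median_offset_um_s: float = 2.0  # between-path median above pooled target
    noise_corr_s: float = 5.0        # AR(1) correlation time of within-path noise

    def __post_init__(self) -> None:
        _check(self.pop_sd_w > 0, "pop_sd_w must be > 0")
        _check(0.0 <= self.between_frac <= 1.0, "between_frac must be in [0, 1]")
        _check(
            self.duration_min_s <= self.duration_median_s <= self.duration_max_s,
            "duration_min_s <= duration_median_s <= duration_max_s violated",
        )
        _check(self.sample_hz > 0, "sample_hz must be > 0")
        _check(self.skew_sign == "negative", "skew_sign must be 'negative'")
        _check(self.mean_speed > 0, "mean_speed must be > 0")
        _check(self.helix_period_s > 0, "helix_period_s must be > 0")
        _check(self.helix_amplitude_frac >= 0, "helix_amplitude_frac must be >= 0")
        _check(self.noise_corr_s > 0, "noise_corr_s must be > 0")

    @property
    def dt(self) -> float:
        return 1.0 / self.sample_hz


@dataclass(frozen=True)
class InitCondition:
    """Initial vertical placement of agents.

    ``kind`` is one of ``bottom-slab`` (uniform on [0, height]), ``point``
    (all agents at z) or ``custom`` (caller supplies positions to
    :func:`planktonwalk.sim.init_population`).
    """

    kind: str = "bottom-slab"
    height_cm: float = 0.5   # slab height for bottom-slab
    z_cm: float = 0.0        # position for point

    def __post_init__(self) -> None:
        _check(self.kind in ("bottom-slab", "point", "custom"),
               f"init kind {self.kind!r} not one of bottom-slab/point/custom")
        if self.kind == "bottom-slab":
            _check(self.height_cm > 0, "bottom-slab height_cm must be > 0")


@dataclass(frozen=True)
class SimConfig:
    """Configuration of the 1-D hidden-Markov correlated random walk.

    ``tau`` is the velocity correlation time: each agent replays the
    vertical velocities of one library trajectory in sequence and is
    reassigned a fresh trajectory with probability ``dt/tau`` per step.
    ``column_height_cm=None`` means an unbounded column.
    """

    tau: float                       # s, correlation time (tau = dt => uncorrelated)
    duration: float                  # s
    dt: float = 0.25                 # s, model iteration interval (4 Hz)
    n_agents: int = 1000
    column_height_cm: float | None = 30.0
    boundary_policy: str = "resample-by-sign"   # or "none"
    init: InitCondition = field(default_factory=InitCondition)
    n_replicates: int = 3
    seed: int = 0
    output_interval: float = 30.0    # s between recorded position snapshots
    replay_mode: str = "wrap"        # or "redraw" when a trajectory is exhausted

    def __post_init__(self) -> None:
        _check(self.tau > 0, "tau must be > 0 (use tau = dt for an uncorrelated walk)")
        _check(self.dt > 0, "dt must be > 0")
        _check(self.n_agents >= 1, "n_agents must be >= 1")
        _check(self.duration >= 0, "duration must be >= 0")
        _check(self.n_replicates >= 1, "n_replicates must be >= 1")
        _check(self.output_interval > 0, "output_interval must be > 0")
        _check(self.replay_mode in ("wrap", "redraw"),
               "replay_mode must be 'wrap' or 'redraw'")
        _check(self.boundary_policy in ("resample-by-sign", "none"),
               "boundary_policy must be 'resample-by-sign' or 'none'")
        if self.column_height_cm is not None:
            _check(self.column_height_cm > 0, "column_height_cm must be > 0")
        nsteps = self.output_interval / self.dt
        _check(abs(nsteps - round(nsteps)) < 1e-9,
               "output_interval must be an integer multiple of dt")

    @property
    def reassignment_probability(self) -> float:
        return min(1.0, self.dt / self.tau)

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


@dataclass(frozen=True)
class SamplingScheme:
    """Virtual stereo-camera sampling design.

    Six horizons ~5 cm apart are each filmed for ``segment_length`` s, one
    pass of all horizons every ``pass_interval`` s, in a horizon order
    randomized once per experiment (``order_seed``).  The camera sees a
    ``window_height`` cm tall slab and an ``observation_volume`` ml subset
    of it, mapping agent counts to organisms per observation.
    """

    horizon_centers_cm: tuple = (2.5, 7.5, 12.5, 17.5, 22.5, 27.5)
    window_height_cm: float = 1.3
    observation_volume_ml: float = 9.0
    tank_volume_ml: float = 1000.0
    segment_length_s: float = 120.0
    pass_interval_s: float = 1500.0     # 25 min, inside the 20–30 min design
    n_passes: int = 3
    start_s: float = 900.0              # filming began 15 min after introduction
    order_seed: int = 0
    poisson: bool = False               # frame-count noise; expected-value mode default

    def __post_init__(self) -> None:
        _check(len(self.horizon_centers_cm) >= 1, "need at least one horizon")
        _check(self.window_height_cm > 0, "window_height_cm must be > 0")
        _check(self.observation_volume_ml > 0, "observation_volume_ml must be > 0")
        _check(self.tank_volume_ml > 0, "tank_volume_ml must be > 0")
        _check(self.segment_length_s > 0, "segment_length_s must be > 0")
        _check(self.n_passes >= 1, "n_passes must be >= 1")
        _check(self.pass_interval_s >= len(self.horizon_centers_cm) * self.segment_length_s,
               "pass_interval_s too short for all horizon segments")

    def validate_against_column(self, column_height_cm: float) -> None:
        for h in self.horizon_centers_cm:
            _check(0.0 <= h <= column_height_cm,
                   f"horizon at {h} cm outside the {column_height_cm} cm column")
        slab_ml = self.tank_volume_ml * self.window_height_cm / column_height_cm
        _check(self.observation_volume_ml <= slab_ml + 1e-9,
               "observation_volume_ml exceeds the slab volume implied by window_height_cm")

    @property
    def total_duration_s(self) -> float:
        """Simulated time needed to cover the full schedule."""
        return (self.start_s + (self.n_passes - 1) * self.pass_interval_s
                + len(self.horizon_centers_cm) * self.segment_length_s)


@dataclass(frozen=True)
class LayerSpec:
    """A thin prey layer inside the water column (metres above the base)."""

    bottom_m: float = 4.0
    thickness_m: float = 1.0

    def __post_init__(self) -> None:
        _check(self.bottom_m >= 0, "layer bottom_m must be >= 0")
        _check(self.thickness_m > 0, "layer thickness_m must be > 0")

    @property
    def top_m(self) -> float:
        return self.bottom_m + self.thickness_m

    def validate_against_column(self, column_height_cm: float) -> None:
        _check(self.top_m * 100.0 <= column_height_cm,
               f"layer top {self.top_m} m outside the {column_height_cm / 100} m column")


def asdict_flat(obj) -> dict:
    """Dataclass -> dict with nested dataclasses flattened one level."""
    out = {}
    for f in fields(obj):
        v = getattr(obj, f.name)
        if hasattr(v, "__dataclass_fields__"):
            out[f.name] = asdict_flat(v)
        elif isinstance(v, tuple):
            out[f.name] = list(v)
        elif isinstance(v, float) and math.isinf(v):
            out[f.name] = "inf"
        else:
            out[f.name] = v
    return out
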