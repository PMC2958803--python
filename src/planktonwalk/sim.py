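"""Individual-based, hidden-Markov, 1-D biased correlated random walk.

Each of ``n_agents`` model organisms carries a vertical position ``z``
(cm), a reference to one library trajectory and a step index within it.
Every time step of length ``dt`` the agent either keeps replaying its
trajectory's vertical velocities in sequence, or — with probability
``dt / tau`` — is reassigned a uniformly drawn fresh trajectory and
restarts at that trajectory's first velocity.  Positions update as
``z(t + dt) = z(t) + w(t) dt``.  ``tau`` is therefore the mean time an
agent keeps one trajectory: the velocity autocorrelation decays as
``exp(-t / tau)``, giving ballistic motion for t << tau and diffusive
motion for t >> tau.  At ``tau = dt`` every step draws a fresh
trajectory (an uncorrelated, biased random walk).

Trajectories (median 5.2 s) are much shorter than the longest correlation
times (up to 1800 s); by default an exhausted trajectory wraps around to
its start (cyclic replay), preserving the cell's identity — and hence
cell-to-cell heterogeneity — until a reassignment fires.  The alternative
``replay_mode="redraw"`` draws a fresh trajectory on exhaustion instead.

Agents crossing a column boundary are clamped to it and reassigned a
trajectory whose net vertical displacement points back into the column
(downward paths at the surface, upward paths at the bottom).

Randomness: each replicate owns one ``numpy`` Generator; per step the
engine draws, in fixed order, one uniform array (reassignment decisions),
one integer array (candidate trajectories) and, per boundary, integers
for the out-of-bounds agents.  This fixed draw order makes runs
bit-reproducible and lets a naive per-agent reference consume the
identical stream.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._units import UM_PER_CM
from .params import ConfigurationError, SimConfig
from .rng import stage_seed_sequence
from .synth import TrajectoryLibrary


class DataError(ValueError):
    """Invalid data encountered mid-simulation (e.g. NaN velocities)."""


@dataclass
class AgentStates:
    """Vectorized state of the whole population at one instant."""

    z: np.ndarray            # cm
    path_ref: np.ndarray     # index into the library
    step_index: np.ndarray   # position within the trajectory's velocity sequence

    @property
    def n_agents(self) -> int:
        return self.z.size

    def copy(self) -> "AgentStates":
        return AgentStates(self.z.copy(), self.path_ref.copy(), self.step_index.copy())


@dataclass
class PopulationTrace:
    """Agent vertical positions over time for one replicate."""

    times: np.ndarray        # s, output grid
    z: np.ndarray            # (n_times, n_agents) cm
    replicate_id: int
    config: SimConfig
    n_reassignments: int = 0

    @property
    def z_matrix(self) -> np.ndarray:
        """Positions as agents × output times."""
        return self.z.T

    @property
    def n_agents(self) -> int:
        return self.z.shape[1]

    def at_time(self, t: float) -> np.ndarray:
        """Agent positions at the output time closest to ``t`` (within dt)."""
        i = int(np.argmin(np.abs(self.times - t)))
        if abs(self.times[i] - t) > self.config.output_interval:
            raise ConfigurationError(f"time {t} s not covered by the trace")
        return self.z[i]


def reassignment_probability(tau: float, dt: float) -> float:
    """Per-step probability of drawing a fresh trajectory: min(1, dt/tau)."""
    if tau <= 0 or dt <= 0:
        raise ConfigurationError("tau and dt must be > 0")
    return min(1.0, dt / tau)


class _Engine:
    """Pre-extracted library arrays + the per-step update."""

    def __init__(self, library: TrajectoryLibrary, config: SimConfig):
        self.config = config
        self.flat, self.start, self.lengths = library.flat_w()
        if np.any(~np.isfinite(self.flat)):
            raise DataError("library contains non-finite velocities")
        self.up, self.down = library.sign_indices()
        if config.column_height_cm is not None and config.boundary_policy == "resample-by-sign":
            if self.up.size == 0 or self.down.size == 0:
                raise ConfigurationError(
                    "resample-by-sign boundary policy needs paths with both "
                    "positive and negative net vertical displacement")
        self.n_paths = self.lengths.size
        self.p_reassign = config.reassignment_probability
        self.step_cm = config.dt / UM_PER_CM

    def current_w(self, states: AgentStates) -> np.ndarray:
        idx = self.start[states.path_ref] + states.step_index % self.lengths[states.path_ref]
        return self.flat[idx]

    def step(self, states: AgentStates, rng: np.random.Generator) -> int:
        """Advance the population by one dt in place; returns #reassignments."""
        cfg = self.config
        n = states.n_agents
        u = rng.random(n)
        candidates = rng.integers(0, self.n_paths, n)
        reassign = u < self.p_reassign
        states.path_ref = np.where(reassign, candidates, states.path_ref)
        states.step_index = np.where(reassign, 0, states.step_index + 1)

        if cfg.replay_mode == "redraw":
            exhausted = (~reassign) & (states.step_index >= self.lengths[states.path_ref])
            if exhausted.any():
                redraw = rng.integers(0, self.n_paths, int(exhausted.sum()))
                states.path_ref[exhausted] = redraw
                states.step_index[exhausted] = 0

        w = self.current_w(states)                       # µm/s
        states.z = states.z + w * self.step_cm           # cm
        self.apply_boundary(states, rng)
        return int(reassign.sum())

    def apply_boundary(self, states: AgentStates, rng: np.random.Generator) -> None:
        cfg = self.config
        if cfg.column_height_cm is None:
            return
        h = cfg.column_height_cm
        if cfg.boundary_policy == "none":
            np.clip(states.z, 0.0, h, out=states.z)
            return
        above = states.z > h
        if above.any():
            k = int(above.sum())
            states.z[above] = h
            states.path_ref[above] = self.down[rng.integers(0, self.down.size, k)]
            states.step_index[above] = 0
        below = states.z < 0.0
        if below.any():
            k = int(below.sum())
            states.z[below] = 0.0
            states.path_ref[below] = self.up[rng.integers(0, self.up.size, k)]
            states.step_index[below] = 0


def init_population(config: SimConfig, library: TrajectoryLibrary,
                    rng: np.random.Generator,
                    custom_z: np.ndarray | None = None) -> AgentStates:
    """Place agents and hand each a uniformly drawn trajectory.

    Each agent starts at step 0 of its trajectory, i.e. with that path's
    first measured vertical velocity.
    """
    n = config.n_agents
    init = config.init
    if init.kind == "bottom-slab":
        z = rng.uniform(0.0, init.height_cm, n)
    elif init.kind == "point":
        z = np.full(n, float(init.z_cm))
    else:  # custom
        if custom_z is None:
            raise ConfigurationError("init kind 'custom' requires custom_z positions")
        z = np.asarray(custom_z, dtype=float).copy()
        if z.size != n:
            raise ConfigurationError("custom_z length must equal n_agents")
    path_ref = rng.integers(0, len(library), n)
    return AgentStates(z=z, path_ref=path_ref,
                       step_index=np.zeros(n, dtype=np.int64))


def step(states: AgentStates, library: TrajectoryLibrary, config: SimConfig,
         rng: np.random.Generator) -> AgentStates:
    """Single-step convenience wrapper around the engine (mutates a copy)."""
    eng = _Engine(library, config)
    out = states.copy()
    eng.step(out, rng)
    return out


def apply_boundary(states: AgentStates, library: TrajectoryLibrary,
                   config: SimConfig, rng: np.random.Generator) -> AgentStates:
    """Apply the column boundary policy to a copy of ``states``."""
    eng = _Engine(library, config)
    out = states.copy()
    eng.apply_boundary(out, rng)
    return out


def run(config: SimConfig, library: TrajectoryLibrary,
        custom_z: np.ndarray | None = None) -> list[PopulationTrace]:
    """Run ``n_replicates`` independent simulations.

    Each replicate draws from its own stream, spawned from
    ``config.seed`` via the stable stage/replicate seed tree, and records
    agent positions every ``output_interval`` s (plus t = 0).  Population
    size is constant throughout.
    """
    eng = _Engine(library, config)
    keep = int(round(config.output_interval / config.dt))
    n_steps = config.n_steps
    traces = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(stage_seed_sequence(config.seed, "sim", rep))
        states = init_population(config, library, rng, custom_z=custom_z)
        snaps = [states.z.copy()]
        times = [0.0]
        total_reassign = 0
        for s in range(n_steps):
            total_reassign += eng.step(states, rng)
            if (s + 1) % keep == 0:
                snaps.append(states.z.copy())
                times.append((s + 1) * config.dt)
        traces.append(PopulationTrace(
            times=np.array(times), z=np.array(snaps), replicate_id=rep,
            config=config, n_reassignments=total_reassign))
    return traces
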