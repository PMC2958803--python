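"""Naive per-agent reference implementation of the correlated random walk.

Deliberately written as explicit Python loops over agents, independent of
the vectorized engine's indexing tricks, but consuming the identical
random stream (one uniform array, one candidate array per step, then
per-boundary integer draws) so results must match bit for bit.
"""

import numpy as np

from planktonwalk._units import UM_PER_CM
from planktonwalk.rng import stage_seed_sequence


def reference_run(config, library):
    """Positions over time for every replicate, matching planktonwalk.sim.run."""
    w_seqs = [p.w for p in library.paths]
    net = [p.net_vertical_displacement_cm for p in library.paths]
    up = [i for i, d in enumerate(net) if d > 0]
    down = [i for i, d in enumerate(net) if d < 0]
    n_paths = len(w_seqs)
    p_re = min(1.0, config.dt / config.tau)
    step_cm = config.dt / UM_PER_CM          # same factorization as the engine
    keep = int(round(config.output_interval / config.dt))
    h = config.column_height_cm

    traces = []
    for rep in range(config.n_replicates):
        rng = np.random.default_rng(stage_seed_sequence(config.seed, "sim", rep))
        n = config.n_agents
        if config.init.kind == "bottom-slab":
            z = list(rng.uniform(0.0, config.init.height_cm, n))
        elif config.init.kind == "point":
            z = [float(config.init.z_cm)] * n
        else:
            raise NotImplementedError
        path = list(rng.integers(0, n_paths, n))
        step_i = [0] * n

        snaps = [list(z)]
        for s in range(config.n_steps):
            u = rng.random(n)
            cand = rng.integers(0, n_paths, n)
            for i in range(n):
                if u[i] < p_re:
                    path[i] = int(cand[i])
                    step_i[i] = 0
                else:
                    step_i[i] += 1
            if config.replay_mode == "redraw":
                exhausted = [i for i in range(n)
                             if u[i] >= p_re and step_i[i] >= len(w_seqs[path[i]])]
                if exhausted:
                    redraw = rng.integers(0, n_paths, len(exhausted))
                    for j, i in enumerate(exhausted):
                        path[i] = int(redraw[j])
                        step_i[i] = 0
            for i in range(n):
                w = w_seqs[path[i]][step_i[i] % len(w_seqs[path[i]])]
                z[i] = z[i] + w * step_cm
            if h is not None and config.boundary_policy == "resample-by-sign":
                above = [i for i in range(n) if z[i] > h]
                if above:
                    draws = rng.integers(0, len(down), len(above))
                    for j, i in enumerate(above):
                        z[i] = h
                        path[i] = down[int(draws[j])]
                        step_i[i] = 0
                below = [i for i in range(n) if z[i] < 0.0]
                if below:
                    draws = rng.integers(0, len(up), len(below))
                    for j, i in enumerate(below):
                        z[i] = 0.0
                        path[i] = up[int(draws[j])]
                        step_i[i] = 0
            elif h is not None:
                z = [min(max(zi, 0.0), h) for zi in z]
            if (s + 1) % keep == 0:
                snaps.append(list(z))
        traces.append(np.array(snaps))
    return traces
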