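import numpy as np
import pytest

from planktonwalk import (SimConfig, TrajectoryLibrary, VelocityModelParams,
                          generate_library, stage_rng)
from planktonwalk.synth import Path3D
from planktonwalk._units import UM_PER_CM

SEED = 0


@pytest.fixture(scope="session")
def params():
    return VelocityModelParams()


@pytest.fixture(scope="session")
def library(params):
    """Default 1032-path synthetic library used across the suite."""
    return generate_library(params, 1032, stage_rng(SEED, "library"))


@pytest.fixture(scope="session")
def small_library(params):
    return generate_library(params, 60, stage_rng(SEED + 1, "library"))


def path_from_w(w_um_s, dt=0.25, path_id="w", uv=None):
    """Build a Path3D whose vertical per-step velocities are exactly w."""
    w = np.asarray(w_um_s, dtype=float)
    n = w.size
    pos = np.zeros((n + 1, 3))
    pos[1:, 2] = np.cumsum(w) * dt / UM_PER_CM
    if uv is not None:
        u, v = uv
        pos[1:, 0] = np.cumsum(np.broadcast_to(u, n)) * dt / UM_PER_CM
        pos[1:, 1] = np.cumsum(np.broadcast_to(v, n)) * dt / UM_PER_CM
    return Path3D(path_id=path_id, times=np.arange(n + 1) * dt, positions=pos)


def library_from_w(*w_sequences, dt=0.25):
    """Library whose paths replay exactly the given vertical velocities."""
    paths = [path_from_w(w, dt=dt, path_id=f"w{i}")
             for i, w in enumerate(w_sequences)]
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")   # sign-coverage warning is expected here
        return TrajectoryLibrary(paths=paths)


def ballistic_path(vel_um_s=(0.0, 0.0, 100.0), n_steps=40, dt=0.25,
                   path_id="ballistic"):
    vel = np.asarray(vel_um_s, dtype=float)
    pos = np.arange(n_steps + 1)[:, None] * vel[None, :] * dt / UM_PER_CM
    return Path3D(path_id=path_id, times=np.arange(n_steps + 1) * dt,
                  positions=pos)


def unbounded(tau, duration, seed=SEED, n_agents=1000, n_replicates=3, **kw):
    kw.setdefault("column_height_cm", None)
    kw.setdefault("boundary_policy", "none")
    return SimConfig(tau=tau, duration=duration, seed=seed, n_agents=n_agents,
                     n_replicates=n_replicates, **kw)
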