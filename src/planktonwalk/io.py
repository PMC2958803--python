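"""CSV and YAML formats.

Track CSV: ``path_id, t_s, x_cm, y_cm, z_cm`` (one file per library).
Summary CSV: ``path_id, duration_s, mean_speed_um_s, mean_angle_deg, mean_w_um_s``.
Trace CSV: ``replicate, t_s, agent_id, z_cm``.
Profile CSV: ``pass, horizon_cm, t_s, count, se``.

All files are UTF-8 with a header row and decimal points; floats are
written with 12 significant digits so a write/read round trip is
lossless at that precision.  YAML configs are validated strictly:
unknown keys are rejected and range errors name the key.
"""

from __future__ import annotations

import hashlib
from dataclasses import fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .params import (ConfigurationError, InitCondition, LayerSpec,
                     SamplingScheme, SimConfig, VelocityModelParams)
from .sampling import AbundanceProfile
from .sim import PopulationTrace
from .synth import Path3D, TrajectoryLibrary

FLOAT_FMT = "%.17g"


# --------------------------------------------------------------------------
# tracks
# --------------------------------------------------------------------------

def write_tracks_csv(library: TrajectoryLibrary, path) -> None:
    frames = []
    for p in library.paths:
        frames.append(pd.DataFrame({
            "path_id": p.path_id,
            "t_s": p.times,
            "x_cm": p.positions[:, 0],
            "y_cm": p.positions[:, 1],
            "z_cm": p.positions[:, 2],
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_tracks_csv(path) -> TrajectoryLibrary:
    df = pd.read_csv(path)
    required = {"path_id", "t_s", "x_cm", "y_cm", "z_cm"}
    missing = required - set(df.columns)
    if missing:
        raise ConfigurationError(f"track CSV missing columns: {sorted(missing)}")
    paths = []
    for pid, grp in df.groupby("path_id", sort=False):
        paths.append(Path3D(
            path_id=str(pid),
            times=grp["t_s"].to_numpy(),
            positions=grp[["x_cm", "y_cm", "z_cm"]].to_numpy()))
    return TrajectoryLibrary(paths=paths)


def write_summary_csv(summaries, path) -> None:
    pd.DataFrame([{
        "path_id": s.path_id,
        "duration_s": s.duration,
        "mean_speed_um_s": s.mean_speed,
        "mean_angle_deg": s.mean_angle_off_vertical,
        "mean_w_um_s": s.mean_w,
    } for s in summaries]).to_csv(path, index=False, float_format=FLOAT_FMT)


# --------------------------------------------------------------------------
# traces
# --------------------------------------------------------------------------

def write_traces_csv(traces: list[PopulationTrace], path) -> None:
    frames = []
    for tr in traces:
        n_t, n_a = tr.z.shape
        frames.append(pd.DataFrame({
            "replicate": np.repeat(tr.replicate_id, n_t * n_a),
            "t_s": np.repeat(tr.times, n_a),
            "agent_id": np.tile(np.arange(n_a), n_t),
            "z_cm": tr.z.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(
        path, index=False, float_format=FLOAT_FMT)


def read_traces_csv(path, config: SimConfig) -> list[PopulationTrace]:
    df = pd.read_csv(path)
    traces = []
    for rep, grp in df.groupby("replicate", sort=True):
        piv = grp.pivot(index="t_s", columns="agent_id", values="z_cm").sort_index()
        traces.append(PopulationTrace(
            times=piv.index.to_numpy(), z=piv.to_numpy(),
            replicate_id=int(rep), config=config))
    return traces


# --------------------------------------------------------------------------
# abundance profiles
# --------------------------------------------------------------------------

def write_profile_csv(profile: AbundanceProfile, path) -> None:
    rows = []
    n_h, n_p = profile.counts.shape
    for p in range(n_p):
        for h in range(n_h):
            rows.append({
                "pass": p + 1,
                "horizon_cm": profile.horizon_centers_cm[h],
                "t_s": profile.times[h, p],
                "count": profile.counts[h, p],
                "se": profile.se[h, p],
            })
    pd.DataFrame(rows).to_csv(path, index=False, float_format=FLOAT_FMT)


def read_profile_csv(path) -> AbundanceProfile:
    df = pd.read_csv(path)
    horizons = np.sort(df["horizon_cm"].unique())
    passes = np.sort(df["pass"].unique())
    shape = (horizons.size, passes.size)
    counts, se, times = (np.zeros(shape) for _ in range(3))
    hidx = {h: i for i, h in enumerate(horizons)}
    pidx = {p: i for i, p in enumerate(passes)}
    for _, row in df.iterrows():
        i, j = hidx[row["horizon_cm"]], pidx[row["pass"]]
        counts[i, j] = row["count"]
        se[i, j] = row["se"]
        times[i, j] = row["t_s"]
    return AbundanceProfile(counts=counts, se=se, times=times,
                            horizon_centers_cm=horizons)


# --------------------------------------------------------------------------
# config
# --------------------------------------------------------------------------

_SECTION_TYPES = {
    "generator": VelocityModelParams,
    "simulation": SimConfig,
    "sampling": SamplingScheme,
    "layer": LayerSpec,
}


def _build_section(cls, data: dict, section: str):
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ConfigurationError(
            f"unknown key(s) {sorted(unknown)} in config section '{section}'")
    kwargs = dict(data)
    if cls is SimConfig and "init" in kwargs and isinstance(kwargs["init"], dict):
        kwargs["init"] = _build_section(InitCondition, kwargs["init"], f"{section}.init")
    if cls is SamplingScheme and "horizon_centers_cm" in kwargs:
        kwargs["horizon_centers_cm"] = tuple(kwargs["horizon_centers_cm"])
    try:
        return cls(**kwargs)
    except ConfigurationError:
        raise
    except TypeError as exc:
        raise ConfigurationError(f"invalid config section '{section}': {exc}") from None


def load_config(path) -> dict:
    """Load and validate a YAML pipeline config.

    Recognized sections: ``generator``, ``simulation``, ``sampling``,
    ``layer``, plus scalar keys ``seed``, ``n_paths`` and ``taus``.
    Unknown sections or keys are rejected; range violations raise a
    :class:`ConfigurationError` naming the offending key.
    """
    p = Path(path)
    if not p.exists():
        raise ConfigurationError(f"config file {p} does not exist")
    raw = yaml.safe_load(p.read_text()) or {}
    known_scalars = {"seed", "n_paths", "taus"}
    unknown = set(raw) - set(_SECTION_TYPES) - known_scalars
    if unknown:
        raise ConfigurationError(f"unknown top-level config key(s): {sorted(unknown)}")
    out = {}
    for section, cls in _SECTION_TYPES.items():
        if section in raw:
            data = raw[section] or {}
            if not isinstance(data, dict):
                raise ConfigurationError(f"config section '{section}' must be a mapping")
            out[section] = _build_section(cls, data, section)
    for key in known_scalars:
        if key in raw:
            out[key] = raw[key]
    return out


def file_digest(path) -> str:
    """sha256 hex digest of a file's bytes."""
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()
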