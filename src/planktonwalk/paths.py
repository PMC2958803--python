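"""Trajectory statistics: smoothing, resampling, movement summaries,
velocity autocorrelation, net distance and skewness.

These mirror the computations applied to laboratory 3-D tracks before any
modelling: cubic-smoothing-spline denoising, subsampling to 4 Hz, per-path
speed/direction summaries, and per-path normalized velocity
autocorrelation with the mean subtracted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from scipy.interpolate import UnivariateSpline

from ._units import UM_PER_CM
from .params import ConfigurationError
from .synth import InsufficientDataError, Path3D

MIN_SUMMARY_DURATION_S = 3.0   # tracks shorter than this are rejected


class UndefinedStatisticError(ValueError):
    """A statistic is undefined for this input (e.g. zero variance)."""


@dataclass(frozen=True)
class PathSummary:
    """Per-path movement summary."""

    path_id: str
    duration: float                   # s
    mean_speed: float                 # µm/s
    mean_angle_off_vertical: float    # degrees, 0 = straight up
    mean_w: float                     # µm/s
    vertical_velocities: np.ndarray   # µm/s per step
    net_distance_curve: np.ndarray    # cm, |pos(t) - pos(0)|, starts at 0
    times: np.ndarray                 # s, grid of the net-distance curve


def smooth_path(path: Path3D, smoothing_level: float) -> Path3D:
    """Cubic smoothing spline per coordinate, evaluated on the same grid.

    ``smoothing_level`` is dimensionless: the spline's residual budget is
    ``smoothing_level * n * var(coordinate)``, so 0 interpolates (positions
    unchanged at the knots) and larger values trade fidelity for
    smoothness.  Linear tracks are reproduced exactly at any level.
    """
    if path.n_samples < 4:
        raise InsufficientDataError("smoothing needs at least 4 samples")
    if smoothing_level < 0:
        raise ConfigurationError("smoothing_level must be >= 0")
    out = np.empty_like(path.positions)
    n = path.n_samples
    for c in range(3):
        coord = path.positions[:, c]
        s = smoothing_level * n * float(np.var(coord))
        spl = UnivariateSpline(path.times, coord, k=3, s=s)
        out[:, c] = spl(path.times)
    return Path3D(path_id=path.path_id, times=path.times.copy(), positions=out)


def resample_path(path: Path3D, interval: float) -> Path3D:
    """Keep every k-th sample, where ``interval`` = k × native interval."""
    ratio = interval / path.dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-6:
        raise ConfigurationError(
            f"interval {interval} s is not an integer multiple of the native "
            f"{path.dt} s sampling interval")
    return Path3D(path_id=path.path_id, times=path.times[::k],
                  positions=path.positions[::k])


def summarize_path(path: Path3D) -> PathSummary:
    """Speed, direction, vertical velocities and net-distance curve.

    The direction is the mean of per-step angles between the velocity and
    the +z axis, so downward steps contribute angles > 90°.
    """
    if path.duration < MIN_SUMMARY_DURATION_S:
        raise InsufficientDataError(
            f"path {path.path_id} is {path.duration:.2f} s long; tracks shorter "
            f"than {MIN_SUMMARY_DURATION_S} s are rejected")
    vel = path.velocities                    # µm/s
    speeds = np.linalg.norm(vel, axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.where(speeds > 0, vel[:, 2] / speeds, np.nan)
    angles = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
    disp = path.positions - path.positions[0]
    net = np.linalg.norm(disp, axis=1)
    return PathSummary(
        path_id=path.path_id,
        duration=path.duration,
        mean_speed=float(speeds.mean()),
        mean_angle_off_vertical=float(np.nanmean(angles)),
        mean_w=float(vel[:, 2].mean()),
        vertical_velocities=vel[:, 2],
        net_distance_curve=net,
        times=path.times - path.times[0],
    )


def cumulative_path_length(path: Path3D) -> np.ndarray:
    """Arc length along the track (cm), same grid as the net-distance curve."""
    steps = np.linalg.norm(np.diff(path.positions, axis=0), axis=1)
    return np.concatenate([[0.0], np.cumsum(steps)])


_COMPONENTS = {"u": 0, "v": 1, "w": 2}


def velocity_autocorrelation(path: Path3D, component: str = "w",
                             max_lag: int | None = None,
                             normalization: str = "biased") -> np.ndarray:
    """Normalized autocovariance of one velocity component by lag.

    Computed per path with the mean velocity subtracted and normalized by
    the lag-0 variance, so the sequence starts at exactly 1.  The default
    biased normalization (divide by n) keeps estimates stable on short
    tracks; ``normalization="unbiased"`` divides by n - lag instead.  The
    default maximum lag is half the number of velocity samples.
    """
    if component not in _COMPONENTS:
        raise ConfigurationError(f"component must be one of {sorted(_COMPONENTS)}")
    if normalization not in ("biased", "unbiased"):
        raise ConfigurationError("normalization must be 'biased' or 'unbiased'")
    x = path.velocities[:, _COMPONENTS[component]]
    n = x.size
    if n < 8:
        raise InsufficientDataError("autocorrelation needs at least 8 velocity samples")
    x = x - x.mean()
    var = float(np.dot(x, x)) / n
    if var <= 0 or np.isclose(var, 0.0, atol=1e-24):
        raise UndefinedStatisticError(
            "velocity component has zero variance; autocorrelation undefined")
    if max_lag is None:
        max_lag = n // 2
    max_lag = min(max_lag, n - 1)
    rho = np.empty(max_lag + 1)
    for lag in range(max_lag + 1):
        acov = float(np.dot(x[: n - lag], x[lag:]))
        denom = n if normalization == "biased" else n - lag
        rho[lag] = acov / denom / var
    return rho


def remove_helix_period(path: Path3D, period_s: float = 1.0) -> Path3D:
    """Suppress the helical oscillation by a one-period moving average.

    Positions are averaged over a window of exactly ``k = period/dt``
    samples, which box-filters the derived velocities over one full helix
    period and therefore cancels any velocity oscillation at that period
    exactly.  The filtered path is ``k - 1`` samples shorter.  Used before
    autocorrelation when the persistent (non-helical) part of the motion
    is of interest.
    """
    k = max(int(round(period_s / path.dt)), 1)
    if k <= 1:
        return path
    n = path.n_samples
    if n <= k:
        raise InsufficientDataError("path shorter than one helix period")
    kernel = np.full(k, 1.0 / k)
    out = np.empty((n - k + 1, 3))
    for c in range(3):
        out[:, c] = np.convolve(path.positions[:, c], kernel, mode="valid")
    times = path.times[: n - k + 1] + (k - 1) * path.dt / 2.0
    return Path3D(path_id=path.path_id, times=times, positions=out)


def sample_skewness(values) -> float:
    """Adjusted Fisher–Pearson standardized third moment."""
    x = np.asarray(values, dtype=float)
    if x.size < 3:
        raise InsufficientDataError("skewness needs at least 3 values")
    if np.var(x) <= 0:
        raise UndefinedStatisticError("skewness undefined for zero variance")
    return float(stats.skew(x, bias=False))


def high_frequency_variance(path: Path3D, component: str = "w") -> float:
    """Velocity variance above half the Nyquist frequency (spectral).

    Diagnostic used to quantify how much high-frequency jitter smoothing
    removes: integrates the velocity periodogram over the top half of the
    frequency axis.
    """
    x = path.velocities[:, _COMPONENTS[component]]
    x = x - x.mean()
    spec = np.abs(np.fft.rfft(x)) ** 2 / x.size
    cut = spec.size // 2
    return float(spec[cut:].sum() / x.size)
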