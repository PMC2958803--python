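"""Virtual observation scheme and model–data comparison statistics.

The virtual camera reproduces the laboratory sampling design: six
horizons ~5 cm apart, each filmed for two minutes per pass, three passes
20–30 minutes apart, horizon order randomized once per experiment.  The
camera's 9-ml stereoscopic volume is mapped to a full-width slab of
height 1.3 cm, so an agent count in the slab converts to an expected
per-observation organism count via the volumetric subsampling factor
``observation_volume / slab_volume``.

Model selection uses the root mean square error between observed and
predicted abundance profiles, scaled to the maximum RMSE across the
correlation-time sweep, compared by one-way ANOVA with a
Bonferroni-corrected post-hoc test at alpha = 0.05.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .params import ConfigurationError, SamplingScheme
from .sim import PopulationTrace


class ComparisonError(ValueError):
    """Profiles or groups are incompatible for comparison."""


class UndefinedStatisticError(ValueError):
    pass


@dataclass
class AbundanceProfile:
    """Organisms per observation: horizons × passes, with SEs and times."""

    counts: np.ndarray              # (n_horizons, n_passes)
    se: np.ndarray                  # same shape
    times: np.ndarray               # (n_horizons, n_passes) segment midpoints, s
    horizon_centers_cm: np.ndarray  # (n_horizons,)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.counts.shape != self.se.shape or self.counts.shape != self.times.shape:
            raise ComparisonError("counts, se and times must share one shape")
        if np.any(self.counts < 0):
            raise ComparisonError("counts must be >= 0")

    @property
    def n_passes(self) -> int:
        return self.counts.shape[1]


def observation_schedule(scheme: SamplingScheme) -> list[tuple[int, int, float]]:
    """(horizon_index, pass_index, segment_start_s) in filming order.

    The horizon order is drawn once from ``order_seed`` and reused for
    every pass, matching a design randomized at the start of the
    experiment.
    """
    order_rng = np.random.default_rng(scheme.order_seed)
    order = order_rng.permutation(len(scheme.horizon_centers_cm))
    schedule = []
    for p in range(scheme.n_passes):
        t0 = scheme.start_s + p * scheme.pass_interval_s
        for slot, h in enumerate(order):
            schedule.append((int(h), p, t0 + slot * scheme.segment_length_s))
    return schedule


def observe(trace: PopulationTrace, scheme: SamplingScheme,
            rng: np.random.Generator | None = None) -> AbundanceProfile:
    """Sample a simulation trace the way the cameras sampled the tank.

    For each scheduled (horizon, pass) segment the expected count is the
    number of agents within ``window_height/2`` of the horizon center,
    averaged over the segment's snapshots, times the volumetric
    subsampling factor.  With ``scheme.poisson`` set, integer counts are
    drawn from a Poisson at the expected value (frame-count noise);
    expected-value mode is the default.
    """
    column = trace.config.column_height_cm
    if column is None:
        raise ConfigurationError("virtual sampling needs a bounded column")
    scheme.validate_against_column(column)
    if scheme.poisson and rng is None:
        raise ConfigurationError("poisson sampling mode requires an rng")
    if trace.times[-1] + 1e-9 < scheme.total_duration_s - scheme.segment_length_s:
        raise ConfigurationError(
            f"trace ends at {trace.times[-1]} s but the sampling schedule "
            f"runs to {scheme.total_duration_s} s")

    slab_volume_ml = scheme.tank_volume_ml * scheme.window_height_cm / column
    vol_factor = scheme.observation_volume_ml / slab_volume_ml
    half = scheme.window_height_cm / 2.0

    n_h = len(scheme.horizon_centers_cm)
    counts = np.zeros((n_h, scheme.n_passes))
    se = np.zeros_like(counts)
    times = np.zeros_like(counts)
    for h, p, t0 in observation_schedule(scheme):
        in_seg = (trace.times >= t0 - 1e-9) & (trace.times <= t0 + scheme.segment_length_s + 1e-9)
        if not in_seg.any():
            raise ConfigurationError(f"no trace snapshots inside segment at {t0} s")
        center = scheme.horizon_centers_cm[h]
        z = trace.z[in_seg]
        frame_counts = np.sum(np.abs(z - center) <= half, axis=1) * vol_factor
        expected = float(frame_counts.mean())
        if scheme.poisson:
            counts[h, p] = rng.poisson(expected)
        else:
            counts[h, p] = expected
        se[h, p] = float(frame_counts.std(ddof=1) / np.sqrt(frame_counts.size)) \
            if frame_counts.size > 1 else 0.0
        times[h, p] = t0 + scheme.segment_length_s / 2.0
    return AbundanceProfile(
        counts=counts, se=se, times=times,
        horizon_centers_cm=np.asarray(scheme.horizon_centers_cm, dtype=float),
        meta={"mode": "poisson" if scheme.poisson else "expected",
              "units": "organisms per observation (counts, not proportions)"})


def rmse(predicted: AbundanceProfile, observed: AbundanceProfile) -> float:
    """Root mean square error over all horizon × pass cells (organisms)."""
    if predicted.counts.shape != observed.counts.shape:
        raise ComparisonError(
            f"profile shapes differ: {predicted.counts.shape} vs {observed.counts.shape}")
    if not np.allclose(predicted.times, observed.times, atol=1e-6):
        raise ComparisonError("profiles were not sampled on the same schedule")
    diff = predicted.counts - observed.counts
    return float(np.sqrt(np.mean(diff ** 2)))


def scale_rmse(rmse_by_tau: dict) -> dict:
    """Divide every raw RMSE by the global maximum (max of output = 1).

    Values may be scalars or per-replicate sequences; scaling is applied
    to the raw values first, so replicate means/SDs computed afterwards
    are means of scaled values (the scaled maximum is exactly 1).
    """
    if not rmse_by_tau:
        raise ComparisonError("empty RMSE mapping")
    arrays = {k: np.atleast_1d(np.asarray(v, dtype=float)) for k, v in rmse_by_tau.items()}
    peak = max(float(a.max()) for a in arrays.values())
    if peak <= 0:
        raise ComparisonError("all RMSE values are zero; scaling degenerate")
    return {k: a / peak for k, a in arrays.items()}


@dataclass(frozen=True)
class OneWayAnovaResult:
    f_statistic: float
    p_value: float
    df_between: int
    df_within: int
    alpha: float
    bonferroni_alpha: float
    pairwise_p: dict          # (label_a, label_b) -> raw p-value
    significant_pairs: dict   # (label_a, label_b) -> bool at Bonferroni alpha


def one_way_anova(groups: dict, alpha: float = 0.05) -> OneWayAnovaResult:
    """Classical one-way ANOVA plus Bonferroni-corrected pairwise t-tests.

    ``groups`` maps labels to sequences of values.  F is computed from the
    between/within sums of squares; each unordered pair of groups is then
    compared with a two-sample t-test at the Bonferroni-adjusted alpha.
    """
    labels = list(groups)
    data = [np.asarray(groups[k], dtype=float) for k in labels]
    if len(data) < 2:
        raise ConfigurationError("one-way ANOVA needs at least 2 groups")
    if any(d.size < 2 for d in data):
        raise ConfigurationError("every group needs at least 2 values")
    n_total = sum(d.size for d in data)
    grand = np.concatenate(data).mean()
    ss_between = sum(d.size * (d.mean() - grand) ** 2 for d in data)
    ss_within = sum(((d - d.mean()) ** 2).sum() for d in data)
    df_b, df_w = len(data) - 1, n_total - len(data)
    if ss_within <= 0:
        if ss_between <= 0:
            raise UndefinedStatisticError("all values identical; F undefined")
        raise UndefinedStatisticError("zero within-group variance; F undefined")
    f = (ss_between / df_b) / (ss_within / df_w)
    p = float(stats.f.sf(f, df_b, df_w))

    pairs = list(itertools.combinations(labels, 2))
    bonf = alpha / len(pairs)
    pairwise_p, significant = {}, {}
    for a, b in pairs:
        t = stats.ttest_ind(groups[a], groups[b])
        pairwise_p[(a, b)] = float(t.pvalue)
        significant[(a, b)] = bool(t.pvalue < bonf)
    return OneWayAnovaResult(
        f_statistic=float(f), p_value=p, df_between=df_b, df_within=df_w,
        alpha=alpha, bonferroni_alpha=bonf,
        pairwise_p=pairwise_p, significant_pairs=significant)


def two_way_anova(values, factor_time, factor_depth) -> pd.DataFrame:
    """Main-effect two-way ANOVA (no interaction term).

    Returns a table with rows ``time`` and ``depth`` and columns
    ``sum_sq, df, F, PR(>F)``.  Degenerate layouts with zero effect and
    zero residual variance report F = 0 for that effect.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({
        "value": np.asarray(values, dtype=float),
        "time": pd.Categorical(factor_time),
        "depth": pd.Categorical(factor_depth),
    })
    if df["value"].isna().any():
        raise ComparisonError("values contain NaN")
    cells = df.groupby(["time", "depth"], observed=True).size()
    if (cells < 1).any():
        raise ComparisonError("empty cells in the two-factor layout")
    model = smf.ols("value ~ C(time) + C(depth)", data=df).fit()
    table = sm.stats.anova_lm(model, typ=2)
    table = table.rename(index={"C(time)": "time", "C(depth)": "depth",
                                "Residual": "residual"})
    # all-equal layouts: effect and residual SS are pure float noise; the
    # F ratio is then meaningless, so report F = 0 instead
    scale = max(float(np.var(df["value"])) * len(df), 1e-300)
    for row in ("time", "depth"):
        degenerate = table.loc[row, "sum_sq"] <= 1e-9 * max(scale, 1e-12)
        if degenerate or np.isnan(table.loc[row, "F"]):
            table.loc[row, "F"] = 0.0
            table.loc[row, "PR(>F)"] = 1.0
    return table
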