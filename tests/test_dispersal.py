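"""Dispersal and prey-layer encounter metrics."""

import numpy as np
import pytest

from planktonwalk import (ConfigurationError, LayerSpec, SimConfig,
                          farthest_quartile_distance, layer_encounter,
                          relative_encounter, sd_growth_slope, sd_over_time,
                          vertical_range)
from planktonwalk.dispersal import SdSeries
from planktonwalk.sim import PopulationTrace

from conftest import SEED


def trace_from_z(z, out_iv=60.0, column=1500.0):
    """PopulationTrace from a (n_times, n_agents) position array."""
    z = np.asarray(z, dtype=float)
    duration = (z.shape[0] - 1) * out_iv
    cfg = SimConfig(tau=1.0, duration=max(duration, out_iv),
                    n_agents=z.shape[1], column_height_cm=column,
                    output_interval=out_iv)
    times = np.arange(z.shape[0]) * out_iv
    return PopulationTrace(times=times, z=z, replicate_id=0, config=cfg)


class TestSdOverTime:
    def test_identical_agents_zero(self):
        tr = trace_from_z(np.full((5, 10), 7.0))
        s = sd_over_time([tr])
        np.testing.assert_array_equal(s.mean_sd, 0.0)

    def test_two_agent_population_convention(self):
        """Two agents at z and z+d: population SD (divide by n) = d/2."""
        tr = trace_from_z(np.array([[1.0, 3.0]]))
        s = sd_over_time([tr])
        assert s.mean_sd[0] == pytest.approx(1.0)

    def test_replicate_mean_and_spread(self):
        t1 = trace_from_z(np.full((3, 4), 0.0) + np.array([0.0, 2.0, 0.0, 2.0]))
        t2 = trace_from_z(np.full((3, 4), 0.0) + np.array([0.0, 4.0, 0.0, 4.0]))
        s = sd_over_time([t1, t2])
        np.testing.assert_allclose(s.mean_sd, 1.5)    # mean of SD 1 and SD 2
        np.testing.assert_allclose(s.sd_sd, 0.5)


class TestSdGrowthSlope:
    def test_constant_series_zero(self):
        s = SdSeries(times=np.arange(10) * 60.0, mean_sd=np.full(10, 2.0),
                     sd_sd=np.zeros(10))
        assert sd_growth_slope(s) == pytest.approx(0.0, abs=1e-12)

    def test_linear_series(self):
        """0.1 cm per minute is exactly 1 mm per minute."""
        t = np.arange(31) * 60.0
        s = SdSeries(times=t, mean_sd=0.1 * t / 60.0, sd_sd=np.zeros_like(t))
        assert sd_growth_slope(s) == pytest.approx(1.0)

    def test_sqrt_series_matches_least_squares_oracle(self):
        """Closed-form LS slope of a*sqrt(t) over a uniform grid."""
        t = np.arange(1, 61) * 30.0
        a = 0.05
        sd = a * np.sqrt(t)
        s = SdSeries(times=t, mean_sd=sd, sd_sd=np.zeros_like(t))
        tb, sb = t.mean(), sd.mean()
        slope = np.sum((t - tb) * (sd - sb)) / np.sum((t - tb) ** 2)
        assert sd_growth_slope(s) == pytest.approx(slope * 600.0)

    def test_window_too_small(self):
        s = SdSeries(times=np.arange(10) * 60.0, mean_sd=np.arange(10.0),
                     sd_sd=np.zeros(10))
        with pytest.raises(ConfigurationError):
            sd_growth_slope(s, window=(0.0, 60.0))

    def test_growth_window_ignores_saturated_tail(self):
        """Linear rise then plateau: the growth fit recovers the rising
        rate, the full-window fit underestimates it."""
        t = np.arange(61) * 60.0
        sd = np.minimum(0.01 * t, 12.0)            # saturates at t = 1200 s
        s = SdSeries(times=t, mean_sd=sd, sd_sd=np.zeros_like(t))
        assert sd_growth_slope(s, window="growth") == pytest.approx(6.0, rel=0.1)
        assert sd_growth_slope(s) < 0.5 * 6.0


class TestVerticalRange:
    def test_identical_agents_zero(self):
        tr = trace_from_z(np.full((2, 100), 3.0))
        assert vertical_range(tr, 60.0) == 0.0

    def test_normal_population_95_span(self):
        rng = np.random.default_rng(SEED)
        z = 100.0 + 10.0 * rng.standard_normal((1, 200_000))
        tr = trace_from_z(z)
        assert vertical_range(tr, 0.0) == pytest.approx(3.92 * 10.0, rel=0.02)

    def test_uniform_population(self):
        z = np.linspace(0.0, 100.0, 100_000)[None, :]
        tr = trace_from_z(z)
        assert vertical_range(tr, 0.0) == pytest.approx(95.0, rel=0.01)
        assert vertical_range(tr, 0.0, mode="minmax") == pytest.approx(100.0)


class TestFarthestQuartile:
    def test_uniform_velocity_population(self):
        """All agents +100 µm/s for 1800 s -> 18 cm."""
        z = np.vstack([np.zeros(100), np.full(100, 18.0)])
        tr = trace_from_z(z, out_iv=1800.0, column=None)
        assert farthest_quartile_distance([tr], 1800.0) == pytest.approx(18.0)

    def test_symmetric_population_uses_absolute_value(self):
        z = np.vstack([np.zeros(100),
                       np.concatenate([np.full(50, 18.0), np.full(50, -18.0)])])
        tr = trace_from_z(z, out_iv=1800.0, column=None)
        assert farthest_quartile_distance([tr], 1800.0) == pytest.approx(18.0)

    def test_matches_brute_force_on_random_trace(self):
        rng = np.random.default_rng(SEED)
        z = np.vstack([np.zeros(400), rng.normal(5.0, 3.0, 400)])
        tr = trace_from_z(z, out_iv=600.0, column=None)
        disp = np.abs(z[1] - z[0])
        brute = np.sort(disp)[-100:].mean()
        assert farthest_quartile_distance([tr], 600.0) == pytest.approx(brute)

    def test_bounded_trace_rejected(self):
        tr = trace_from_z(np.zeros((2, 10)), column=30.0)
        with pytest.raises(ConfigurationError, match="unbounded"):
            farthest_quartile_distance([tr], 60.0)


def ramp_trace(speeds_um_s, duration=86_400.0, out_iv=60.0, column=1500.0):
    """Agents rising at constant speed (µm/s each) from z=0."""
    times = np.arange(0.0, duration + out_iv / 2, out_iv)
    z = np.minimum(times[:, None] * np.asarray(speeds_um_s)[None, :] * 1e-4,
                   column)
    return trace_from_z(z, out_iv=out_iv, column=column)


class TestLayerEncounter:
    def test_constant_velocity_arrival(self):
        """100 µm/s to a layer at 1 m: arrival at 1e4 s ≈ 2.78 h."""
        tr = ramp_trace(np.full(100, 100.0))
        enc = layer_encounter([tr], LayerSpec(bottom_m=1.0), fraction=0.25)
        assert enc.arrival_time_s == pytest.approx(1.0e4, abs=60.0)

    def test_layer_spanning_column(self):
        tr = ramp_trace(np.full(40, 100.0), duration=3600.0, column=1500.0)
        enc = layer_encounter([tr], LayerSpec(bottom_m=0.0, thickness_m=15.0))
        assert enc.arrival_time_s == 0.0
        assert enc.residence_s == pytest.approx(3600.0, abs=1.0)

    def test_two_speed_population_arrival_set_by_fast_quarter(self):
        speeds = np.concatenate([np.full(25, 200.0), np.full(75, 50.0)])
        tr = ramp_trace(speeds)
        enc = layer_encounter([tr], LayerSpec(bottom_m=1.0), fraction=0.25)
        assert enc.arrival_time_s == pytest.approx(1.0e6 / 200.0, abs=60.0)

    def test_occupancy_mode(self):
        """Constant 100 µm/s through a 1-m layer: occupancy = 1e4 s."""
        tr = ramp_trace(np.full(50, 100.0))
        enc = layer_encounter([tr], LayerSpec(bottom_m=1.0), fraction=0.25,
                              residence_mode="occupancy")
        assert enc.residence_s == pytest.approx(1.0e4, rel=0.02)

    def test_fraction_never_reached_flagged_absent(self):
        tr = ramp_trace(np.full(20, 5.0), duration=3600.0)   # far too slow
        enc = layer_encounter([tr], LayerSpec(bottom_m=4.0), fraction=0.25)
        assert not enc.reached
        assert np.isnan(enc.residence_s)

    def test_presence_window_extends_with_staggered_cohort(self):
        """Equal crossing speeds, staggered entries: per-agent occupancy is
        unchanged but the cohort maintains a presence in the layer for the
        whole staggered window."""
        out_iv = 60.0
        times = np.arange(0.0, 86_400.0 + out_iv / 2, out_iv)

        def crossing(starts):
            # rises at 100 µm/s from z=50 cm, delayed per agent
            z = 50.0 + np.clip(times[:, None] - np.asarray(starts)[None, :],
                               0.0, None) * 100.0 * 1e-4
            return trace_from_z(z, out_iv=out_iv)

        layer = LayerSpec(bottom_m=1.0)
        sync = layer_encounter([crossing([0.0] * 4)], layer, fraction=1.0)
        stag = layer_encounter([crossing([0.0, 5e3, 1e4, 1.5e4])], layer,
                               fraction=1.0)
        assert sync.residence_s == pytest.approx(1.0e4, abs=2 * out_iv)
        assert stag.residence_s == pytest.approx(2.5e4, abs=2 * out_iv)
        occ_sync = layer_encounter([crossing([0.0] * 4)], layer, fraction=1.0,
                                   residence_mode="occupancy").residence_s
        occ_stag = layer_encounter([crossing([0.0, 5e3, 1e4, 1.5e4])], layer,
                                   fraction=1.0,
                                   residence_mode="occupancy").residence_s
        assert occ_stag == pytest.approx(occ_sync, rel=0.02)


class TestRelativeEncounter:
    def _enc(self, arrival_h, residence_h, mode="presence"):
        from planktonwalk.dispersal import EncounterSummary
        return EncounterSummary(arrival_time_s=arrival_h * 3600.0,
                                residence_s=residence_h * 3600.0,
                                fraction=0.25, residence_mode=mode,
                                per_replicate_arrival_s=np.array([arrival_h * 3600.0]),
                                per_replicate_residence_s=np.array([residence_h * 3600.0]))

    def test_identical_inputs_zero(self):
        e = self._enc(10.0, 3.0)
        assert relative_encounter(e, e) == (0.0, 0.0)

    def test_known_offsets(self):
        adv, exc = relative_encounter(self._enc(8.0, 6.0), self._enc(10.0, 3.0))
        assert adv == pytest.approx(2.0)    # arrived 2 h earlier
        assert exc == pytest.approx(3.0)    # stayed 3 h longer

    def test_sign_convention_earlier_arrival_positive(self):
        adv, _ = relative_encounter(self._enc(5.0, 1.0), self._enc(9.0, 1.0))
        assert adv > 0

    def test_mismatched_modes_rejected(self):
        with pytest.raises(ConfigurationError):
            relative_encounter(self._enc(5.0, 1.0),
                               self._enc(5.0, 1.0, mode="occupancy"))


def test_summarize_dispersal_aggregate(small_library):
    from planktonwalk import SimConfig, run, summarize_dispersal
    cfg = SimConfig(tau=100.0, duration=600.0, n_agents=100, seed=SEED,
                    column_height_cm=30.0, n_replicates=2)
    s = summarize_dispersal(run(cfg, small_library),
                            layer=LayerSpec(bottom_m=0.01, thickness_m=0.05))
    assert s.sd_series.mean_sd.shape == (21,)
    assert s.range_95_cm > 0
    assert np.isnan(s.quartile_mean_distance_cm)   # bounded column
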