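"""Correlated-random-walk engine: reassignment rule, boundary policy,
replay modes, conservation, and exact equivalence with a naive
per-agent reference implementation."""

import dataclasses

import numpy as np
import pytest

from planktonwalk import (ConfigurationError, InitCondition, SimConfig,
                          init_population, reassignment_probability, run,
                          stage_rng)
from planktonwalk.sim import apply_boundary, AgentStates, step

from conftest import SEED, library_from_w, unbounded
from reference import reference_run


class TestReassignmentProbability:
    def test_uncorrelated_limit(self):
        assert reassignment_probability(0.25, 0.25) == 1.0

    def test_forced_arithmetic(self):
        assert reassignment_probability(1800.0, 0.25) == pytest.approx(
            0.25 / 1800.0)

    def test_capped_at_one(self):
        assert reassignment_probability(0.1, 0.25) == 1.0

    def test_nonpositive_rejected(self):
        with pytest.raises(ConfigurationError):
            reassignment_probability(0.0, 0.25)
        with pytest.raises(ConfigurationError):
            reassignment_probability(10.0, -1.0)


class TestInitPopulation:
    def test_point_init(self, small_library):
        cfg = SimConfig(tau=1.0, duration=10.0, n_agents=1000,
                        init=InitCondition(kind="point", z_cm=0.0))
        s = init_population(cfg, small_library, stage_rng(SEED, "sim"))
        assert np.all(s.z == 0.0)
        assert np.all(s.step_index == 0)

    def test_bottom_slab_uniform(self, small_library):
        cfg = SimConfig(tau=1.0, duration=10.0, n_agents=10_000,
                        init=InitCondition(kind="bottom-slab", height_cm=2.0))
        s = init_population(cfg, small_library, stage_rng(SEED, "sim"))
        assert s.z.min() >= 0.0 and s.z.max() <= 2.0
        assert s.z.mean() == pytest.approx(1.0, abs=3 * 2.0 / np.sqrt(12e4))

    def test_single_path_library_first_velocity(self):
        lib = library_from_w(np.array([120.0, -40.0, 60.0, 80.0] * 4))
        cfg = unbounded(1.0, 10.0, n_agents=20)
        rng = stage_rng(SEED, "sim")
        s = init_population(cfg, lib, rng)
        from planktonwalk.sim import _Engine
        w0 = _Engine(lib, cfg).current_w(s)
        assert np.all(w0 == 120.0)


class TestStepAndBoundary:
    def test_constant_velocity_exact_displacement(self):
        """Single constant-w path, no reassignment: 100 µm/s × 1800 s = 18 cm."""
        lib = library_from_w(np.full(16, 100.0))
        cfg = unbounded(1e12, 1800.0, n_agents=100, n_replicates=1,
                        init=InitCondition(kind="point", z_cm=0.0))
        tr = run(cfg, lib)[0]
        np.testing.assert_allclose(tr.z[-1], 18.0, rtol=1e-12)
        assert tr.n_reassignments == 0

    def test_uncorrelated_reassigns_every_step(self, small_library):
        cfg = unbounded(0.25, 25.0, n_agents=50, n_replicates=1)
        tr = run(cfg, small_library)[0]
        assert tr.n_reassignments == 50 * 100

    def test_reassignment_frequency_matches_geometric_oracle(self, small_library):
        """tau=300 s: reassignment count ≈ n_steps·n_agents·dt/tau within
        3 binomial SDs, so the mean inter-reassignment time ≈ tau."""
        cfg = unbounded(300.0, 250.0, n_agents=1000, n_replicates=1)
        tr = run(cfg, small_library)[0]
        n_trials = cfg.n_steps * cfg.n_agents
        p = cfg.dt / 300.0
        expected = n_trials * p
        sd = np.sqrt(n_trials * p * (1 - p))
        assert abs(tr.n_reassignments - expected) < 3 * sd
        mean_interval = n_trials * cfg.dt / tr.n_reassignments
        assert mean_interval == pytest.approx(300.0, rel=0.12)

    def test_boundary_clamps_and_resamples_by_sign(self, library):
        cfg = SimConfig(tau=10.0, duration=10.0, n_agents=4,
                        column_height_cm=30.0)
        states = AgentStates(z=np.array([30.1, -0.05, 15.0, 29.9]),
                             path_ref=np.zeros(4, dtype=np.int64),
                             step_index=np.zeros(4, dtype=np.int64))
        out = apply_boundary(states, library, cfg, stage_rng(SEED, "sim"))
        net = library.net_vertical_displacements
        assert out.z[0] == 30.0 and net[out.path_ref[0]] < 0   # sent downward
        assert out.z[1] == 0.0 and net[out.path_ref[1]] > 0    # sent upward
        assert out.z[2] == 15.0 and out.path_ref[2] == 0       # untouched
        assert out.step_index[0] == 0 and out.step_index[1] == 0

    def test_unbounded_boundary_is_identity(self, library):
        cfg = unbounded(10.0, 10.0, n_agents=3)
        states = AgentStates(z=np.array([-5.0, 15.0, 4000.0]),
                             path_ref=np.zeros(3, dtype=np.int64),
                             step_index=np.ones(3, dtype=np.int64))
        out = apply_boundary(states, library, cfg, stage_rng(SEED, "sim"))
        np.testing.assert_array_equal(out.z, states.z)

    def test_missing_sign_fails_at_start_not_midrun(self):
        lib = library_from_w(np.full(16, 100.0), np.full(16, 50.0))  # all upward
        cfg = SimConfig(tau=1.0, duration=10.0, n_agents=5, column_height_cm=30.0)
        with pytest.raises(ConfigurationError, match="negative"):
            run(cfg, lib)

    def test_bounded_constant_velocity_never_exits(self):
        """Up/down constant paths in a bounded column: agents oscillate
        between the walls and never leave [0, H]."""
        lib = library_from_w(np.full(8, 400.0), np.full(8, -400.0))
        cfg = SimConfig(tau=1e12, duration=4000.0, n_agents=20,
                        column_height_cm=10.0, seed=SEED,
                        init=InitCondition(kind="point", z_cm=5.0),
                        n_replicates=1)
        tr = run(cfg, lib)[0]
        assert tr.z.min() >= 0.0 and tr.z.max() <= 10.0
        assert tr.z.std() > 0      # actually moving

    def test_step_wrapper_advances_indices(self, small_library):
        cfg = unbounded(1e12, 10.0, n_agents=6)
        rng = stage_rng(SEED, "sim")
        s0 = init_population(cfg, small_library, rng)
        s1 = step(s0, small_library, cfg, rng)
        assert np.all(s1.step_index == 1)
        assert np.all(s0.step_index == 0)   # input untouched


class TestRun:
    def test_zero_duration_returns_initial_condition(self, small_library):
        cfg = unbounded(1.0, 0.0, n_agents=30, n_replicates=2)
        for tr in run(cfg, small_library):
            assert tr.z.shape == (1, 30)
            assert tr.times[0] == 0.0

    def test_population_size_constant(self, small_library):
        cfg = SimConfig(tau=10.0, duration=120.0, n_agents=64, seed=SEED,
                        column_height_cm=30.0)
        for tr in run(cfg, small_library):
            assert tr.z.shape[1] == 64
            assert np.all(np.isfinite(tr.z))

    def test_bit_reproducible(self, small_library):
        cfg = SimConfig(tau=5.0, duration=60.0, n_agents=40, seed=123,
                        column_height_cm=30.0)
        a = run(cfg, small_library)
        b = run(cfg, small_library)
        for ta, tb in zip(a, b):
            np.testing.assert_array_equal(ta.z, tb.z)

    def test_replicates_differ(self, small_library):
        cfg = SimConfig(tau=5.0, duration=60.0, n_agents=40, seed=123,
                        column_height_cm=30.0, n_replicates=2)
        a, b = run(cfg, small_library)
        assert not np.array_equal(a.z[-1], b.z[-1])

    @pytest.mark.parametrize("replay_mode", ["wrap", "redraw"])
    @pytest.mark.parametrize("bounded", [True, False])
    def test_matches_naive_reference_exactly(self, small_library, replay_mode,
                                             bounded):
        """Vectorized engine == per-agent reference, bit for bit."""
        cfg = SimConfig(tau=2.0, duration=25.0, n_agents=10, seed=77,
                        column_height_cm=30.0 if bounded else None,
                        boundary_policy="resample-by-sign" if bounded else "none",
                        n_replicates=2, replay_mode=replay_mode,
                        output_interval=0.25)
        traces = run(cfg, small_library)
        refs = reference_run(cfg, small_library)
        for tr, ref in zip(traces, refs):
            np.testing.assert_array_equal(tr.z, ref)

    def test_wrap_vs_redraw_differ_for_long_tau(self, small_library):
        base = dict(duration=200.0, n_agents=50, seed=5)
        wrap = run(unbounded(1e6, **base, replay_mode="wrap"), small_library)[0]
        redraw = run(unbounded(1e6, **base, replay_mode="redraw"), small_library)[0]
        # wrap preserves per-agent identity -> far larger population spread
        assert wrap.z[-1].std() > 2.0 * redraw.z[-1].std()

    def test_tau_below_dt_equivalent_to_tau_dt(self, small_library):
        a = run(unbounded(0.25, 30.0, n_agents=30, n_replicates=1), small_library)[0]
        b = run(unbounded(0.1, 30.0, n_agents=30, n_replicates=1), small_library)[0]
        np.testing.assert_array_equal(a.z, b.z)
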