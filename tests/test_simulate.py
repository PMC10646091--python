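"""Synthetic navigator simulator: design constraints, strategies, determinism."""

import math

import numpy as np
import pytest

from mazemetrics import (AgentSpec, ArenaConfig, generate_design,
                         memory_score, memory_score_analytic, path_error,
                         simulate_block, simulate_cohort, simulate_trial,
                         surface_coverage, trajectory_distance)
from mazemetrics.simulate import (N_LEARNING, N_PROBE, PROBE_ROTATIONS,
                                  START_ANGLES, start_location)


def noiseless_agent(**kw):
    base = dict(strategy="direct", goal_noise_sigma=0.0,
                heading_noise_sigma=0.0, scan_duration=0.0, seed=1)
    base.update(kw)
    return AgentSpec(**base)


class TestDesign:
    def test_six_blocks_with_task_structure(self, arena):
        design = generate_design(arena, seed=5)
        assert len(design.blocks) == 6
        assert sorted(b.start_angle for b in design.blocks) == \
            sorted(START_ANGLES)
        for b in design.blocks:
            assert sorted(b.probe_rotations) == sorted(PROBE_ROTATIONS)

    def test_target_center_distance_in_sampling_interval(self, arena):
        for seed in range(20):
            for b in generate_design(arena, seed).blocks:
                d = math.hypot(*b.target_location)
                assert 0.2 * arena.radius <= d <= 0.8 * arena.radius

    def test_target_on_quadrant_center_axis(self, arena):
        for b in generate_design(arena, seed=9).blocks:
            ang = math.degrees(math.atan2(b.target_location[1],
                                          b.target_location[0]))
            rel = (ang - b.start_angle) % 360
            assert min(abs(rel - a) for a in (45, 135, 225, 315)) < 1e-9

    def test_same_seed_identical_design(self, arena):
        assert generate_design(arena, 3) == generate_design(arena, 3)

    def test_probe_start_is_rotated_about_center(self, arena):
        b = generate_design(arena, 1).blocks[0]
        s0 = start_location(b, arena, 0.0)
        s180 = start_location(b, arena, 180.0)
        np.testing.assert_allclose(s180, -s0, atol=1e-12)


class TestSimulateTrial:
    def test_noiseless_direct_agent_is_optimal(self, arena):
        """No goal/heading noise, no scanning: straight path, perfect recall."""
        design = generate_design(arena, seed=2)
        agent = noiseless_agent()
        for rot in PROBE_ROTATIONS:
            meta, traj = simulate_trial(design.blocks[0], "probe", rot, agent,
                                        arena)
            assert path_error(traj) == pytest.approx(0.0, abs=0.1)
            score = memory_score(traj.final_location, meta.target_location,
                                 arena, seed=11)
            assert score.score == 100.0

    def test_learning_trial_stops_at_capture_radius(self, arena):
        design = generate_design(arena, seed=2)
        meta, traj = simulate_trial(design.blocks[0], "learning", None,
                                    noiseless_agent(), arena)
        d = np.linalg.norm(traj.final_location
                           - np.asarray(meta.target_location))
        assert d <= 0.8 + 1e-9
        assert meta.probe_rotation is None

    def test_replication_on_180_probe_reflects_final_through_center(self, arena):
        """Egocentric replay from the opposite start lands at the point
        reflection of the learned final location, scoring below chance."""
        design = generate_design(arena, seed=4)
        agent = noiseless_agent(strategy="path_replication")
        trials = simulate_block(design.blocks[0], agent, arena)
        learned_final = trials[N_LEARNING - 1][1].final_location
        probe_180 = next(t for m, t in trials[N_LEARNING:]
                         if m.probe_rotation == 180.0)
        np.testing.assert_allclose(probe_180.final_location, -learned_final,
                                   atol=1e-9)
        meta = trials[0][0]
        assert memory_score_analytic(probe_180.final_location,
                                     meta.target_location, arena) < 50.0

    def test_replication_requires_prior_learning_trial(self, arena):
        design = generate_design(arena, seed=4)
        agent = noiseless_agent(strategy="path_replication")
        with pytest.raises(ValueError, match="learning"):
            simulate_trial(design.blocks[0], "probe", 90.0, agent, arena,
                           learned=None)

    def test_random_search_covers_more_surface_than_direct(self, arena):
        """Paired over seeded trials: the random walker's bounding box beats
        the goal-directed agent's."""
        design = generate_design(arena, seed=6)
        wins = 0
        for seed in range(50):
            rng_a = np.random.default_rng(seed)
            rng_b = np.random.default_rng(seed)
            _, direct = simulate_trial(
                design.blocks[seed % 6], "probe", 90.0,
                AgentSpec(strategy="direct", seed=seed), arena, rng=rng_a)
            _, search = simulate_trial(
                design.blocks[seed % 6], "probe", 90.0,
                AgentSpec(strategy="random_search", max_duration=30.0,
                          seed=seed), arena, rng=rng_b)
            if surface_coverage(search, arena) > surface_coverage(direct, arena):
                wins += 1
        assert wins == 50

    def test_trajectories_respect_the_wall(self, arena):
        design = generate_design(arena, seed=8)
        for strat in ("direct", "random_search"):
            agent = AgentSpec(strategy=strat, max_duration=20.0, seed=3)
            _, traj = simulate_trial(design.blocks[1], "probe", 270.0, agent,
                                     arena)
            r = np.linalg.norm(traj.positions, axis=1)
            assert r.max() <= arena.radius + 1e-9

    def test_sampling_rate_sets_time_grid(self, arena):
        design = generate_design(arena, seed=2)
        _, traj = simulate_trial(design.blocks[0], "probe", 0.0,
                                 noiseless_agent(sampling_rate=90.0), arena)
        np.testing.assert_allclose(np.diff(traj.timestamps), 1 / 90)


class TestParameterRecovery:
    def test_memory_score_decreases_with_goal_noise(self, arena):
        """Mean memory score is monotone decreasing on the noise grid."""
        design = generate_design(arena, seed=10)
        means = []
        for sigma in (0.0, 0.5, 1.0, 2.0):
            scores = []
            for k in range(100):
                agent = noiseless_agent(goal_noise_sigma=sigma)
                meta, traj = simulate_trial(
                    design.blocks[k % 6], "probe",
                    PROBE_ROTATIONS[k % 4], agent, arena,
                    rng=np.random.default_rng(1000 + k))
                scores.append(memory_score_analytic(
                    traj.final_location, meta.target_location, arena))
            means.append(np.mean(scores))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_idphi_increases_with_scan_duration(self, arena):
        from mazemetrics import initial_angular_velocity
        design = generate_design(arena, seed=10)
        means = []
        for scan in (0.0, 2.0, 5.0):
            vals = []
            for k in range(30):
                agent = noiseless_agent(scan_duration=scan,
                                        goal_noise_sigma=0.3)
                _, traj = simulate_trial(
                    design.blocks[k % 6], "probe", 90.0, agent, arena,
                    rng=np.random.default_rng(2000 + k))
                vals.append(initial_angular_velocity(traj, arena))
            means.append(np.mean(vals))
        assert means[0] < means[1] < means[2]

    def test_replication_agents_replay_better_than_direct(self, arena):
        """On rotated probes, replication agents have strictly lower mean
        trajectory distance than direct agents in >= 90% of seeded pairs."""
        design = generate_design(arena, seed=10)
        wins = 0
        n_pairs = 50
        for seed in range(n_pairs):
            block = design.blocks[seed % 6]
            dists = {}
            for strat in ("path_replication", "direct"):
                agent = AgentSpec(strategy=strat, goal_noise_sigma=0.3,
                                  heading_noise_sigma=0.01,
                                  scan_duration=1.0, seed=seed)
                trials = simulate_block(block, agent, arena,
                                        rng=np.random.default_rng(seed))
                learn = trials[N_LEARNING - 1][1]
                rotated = [(m, t) for m, t in trials[N_LEARNING:]
                           if m.probe_rotation in (90.0, 180.0, 270.0)]
                dists[strat] = np.mean([
                    trajectory_distance(learn, t, arena) for _, t in rotated])
            if dists["path_replication"] < dists["direct"]:
                wins += 1
        assert wins >= 0.9 * n_pairs


class TestCohort:
    def test_shapes_and_determinism(self, arena, tmp_path):
        m1 = simulate_cohort(n_per_group=(2, 3), seed=9,
                             out_dir=tmp_path / "a")
        m2 = simulate_cohort(n_per_group=(2, 3), seed=9,
                             out_dir=tmp_path / "b")
        assert len(m1["files"]["trajectories"]) == 5 * 2  # participants x setups
        for f1, f2 in zip(m1["files"]["trajectories"] + m1["files"]["meta"],
                          m2["files"]["trajectories"] + m2["files"]["meta"]):
            assert (tmp_path / "a" / f1.split("/")[-1]).read_bytes() == \
                (tmp_path / "b" / f2.split("/")[-1]).read_bytes()

    def test_each_session_has_42_trials(self, arena, tmp_path):
        import pandas as pd
        simulate_cohort(n_per_group=(1, 1), seed=3, out_dir=tmp_path)
        meta = pd.read_csv(tmp_path / "p01_stationary_meta.csv")
        assert len(meta) == 6 * (N_LEARNING + N_PROBE)
        assert (meta.groupby("block")["trial_type"].value_counts()
                .unstack()[["learning", "probe"]].values
                == [N_LEARNING, N_PROBE]).all()

    def test_group_effects_order_memory_scores(self, arena, tmp_path):
        """A goal-noise interaction yields MTLR-stationary as worst cell."""
        from mazemetrics import run_pipeline
        simulate_cohort(n_per_group=(3, 3), seed=21, out_dir=tmp_path / "c")
        metrics, summary = run_pipeline(tmp_path / "c", arena,
                                        tmp_path / "out", seed=21)
        ms = summary[(summary.metric == "memory_score")
                     & (summary.trial_type == "probe")]
        cells = {(g, s): v for g, s, v in zip(ms["group"], ms["setup"],
                                              ms["mean"])}
        assert cells[("MTLR", "stationary")] == min(cells.values())
        assert cells[("MTLR", "mobile")] > cells[("MTLR", "stationary")]
        assert cells[("control", "mobile")] > cells[("control", "stationary")]
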