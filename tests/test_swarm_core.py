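"""Swarm state, inertia schedule, best-position bookkeeping, main loop."""

import dataclasses

import numpy as np
import pytest

from swarmselect import (
    SwarmConfig,
    initialize_swarm,
    random_stream,
    run_optimizer,
    update_bests,
    update_inertia,
)


class TestConfig:
    def test_defaults_match_protocol(self):
        cfg = SwarmConfig()
        assert cfg.num_particles == 100
        assert cfg.max_iter == 500
        assert cfg.c1 == cfg.c2 == 2.0
        assert (cfg.w1, cfg.w2) == (0.8, 0.2)
        assert cfg.w_init == 1.4

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"max_iter": 0},
            {"num_particles": 0},
            {"c1": 2.5},
            {"c2": -0.1},
            {"w1": 0.5, "w2": 0.5},       # outside the allowed [0.6, 0.9]
            {"w1": 0.8, "w2": 0.3},       # weights must sum to 1
            {"v_max_fraction": 0.0},
            {"sigmoid_steepness": 0.0},
            {"init_bit_prob": 1.5},
            {"speed_init_range": (1.0, 0.5)},
            {"min_set_prob": 0.7},
        ],
    )
    def test_invalid_configuration_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SwarmConfig(**kwargs)

    def test_yaml_round_trip(self, tmp_path):
        cfg = SwarmConfig(num_particles=7, max_iter=11, w1=0.7, w2=0.3, seed=42)
        path = tmp_path / "cfg.yaml"
        cfg.to_file(path)
        assert SwarmConfig.from_file(path) == cfg

    def test_unknown_config_key_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("bogus: 1\n")
        with pytest.raises(ValueError, match="bogus"):
            SwarmConfig.from_file(path)


class TestInertia:
    @pytest.mark.parametrize(
        "w, iteration, max_iter, expected",
        [
            (1.4, 500, 500, 0.4),   # bracket vanishes, floor remains
            (1.4, 0, 500, 1.4),     # identity at iteration 0
            (1.4, 0, 123, 1.4),
            (1.4, 250, 500, 0.9),   # (1.4-0.4)*0.5 + 0.4
        ],
    )
    def test_update_examples(self, w, iteration, max_iter, expected):
        cfg = SwarmConfig(max_iter=max_iter)
        assert update_inertia(w, iteration, cfg) == pytest.approx(expected, abs=1e-12)

    def test_iteration_out_of_range(self):
        cfg = SwarmConfig(max_iter=10)
        with pytest.raises(ValueError):
            update_inertia(1.4, 11, cfg)

    def test_recurrence_decays_nonlinearly_within_bounds(self):
        cfg = SwarmConfig(max_iter=50)
        w, seq = cfg.w_init, []
        for t in range(cfg.max_iter):
            seq.append(w)
            w = update_inertia(w, t, cfg)
        seq.append(w)
        assert all(a >= b for a, b in zip(seq, seq[1:]))
        assert all(cfg.w_floor <= x <= cfg.w_init for x in seq)
        # nonlinear: drops faster than the linear ramp at mid-schedule
        linear_mid = cfg.w_init - (cfg.w_init - cfg.w_floor) * 0.5
        assert seq[25] < linear_mid


class TestInitializeSwarm:
    @pytest.mark.parametrize("p, total", [(0.0, 0), (1.0, None)])
    def test_bit_probability_extremes(self, p, total):
        cfg = SwarmConfig(num_particles=6, max_iter=5, init_bit_prob=p)
        swarm = initialize_swarm(20, cfg, random_stream(0), "bpso")
        expected = 0 if total == 0 else 6 * 20
        assert int(swarm.positions.sum()) == expected

    @pytest.mark.parametrize("variant", ["bpso", "epso"])
    def test_same_seed_same_swarm(self, variant, small_config):
        a = initialize_swarm(15, small_config, random_stream(7), variant)
        b = initialize_swarm(15, small_config, random_stream(7), variant)
        np.testing.assert_array_equal(a.positions, b.positions)
        if variant == "bpso":
            np.testing.assert_array_equal(a.velocities, b.velocities)
        else:
            np.testing.assert_array_equal(a.speeds, b.speeds)

    def test_motion_state_ranges(self, small_config):
        n = 30
        bpso = initialize_swarm(n, small_config, random_stream(1), "bpso")
        v_max = small_config.v_max(n)
        assert np.all(np.abs(bpso.velocities) <= v_max)
        epso = initialize_swarm(n, small_config, random_stream(1), "epso")
        lo, hi = small_config.speed_init_range
        assert np.all(epso.speeds > lo) and np.all(epso.speeds <= hi)

    def test_pbest_starts_at_initial_position(self, small_config):
        swarm = initialize_swarm(10, small_config, random_stream(2), "epso")
        np.testing.assert_array_equal(swarm.positions, swarm.pbest_positions)
        assert np.all(np.isneginf(swarm.pbest_fitness))


class TestUpdateBests:
    def _swarm(self):
        cfg = SwarmConfig(num_particles=2, max_iter=2)
        swarm = initialize_swarm(4, cfg, random_stream(0), "bpso")
        swarm.pbest_fitness[:] = 0.8
        return swarm

    def test_strict_improvement_replaces(self):
        swarm = self._swarm()
        swarm.positions[0] = [1, 0, 0, 0]
        assert update_bests(swarm, 0, 0.9, 1.0)
        assert swarm.pbest_fitness[0] == 0.9
        np.testing.assert_array_equal(swarm.pbest_positions[0], [1, 0, 0, 0])

    def test_tie_keeps_incumbent(self):
        swarm = self._swarm()
        incumbent = swarm.pbest_positions[1].copy()
        assert not update_bests(swarm, 1, 0.8, 1.0)
        np.testing.assert_array_equal(swarm.pbest_positions[1], incumbent)


class TestRunOptimizer:
    def test_single_particle_single_iteration(self, tiny_dataset):
        cfg = SwarmConfig(num_particles=1, max_iter=1, seed=5)
        result = run_optimizer(tiny_dataset, cfg, "bpso")
        assert len(result.trajectory) == 1
        # with one particle the global best is its personal best
        assert result.gbest_num_genes == int(result.gbest_position.sum())

    @pytest.mark.parametrize("variant", ["bpso", "epso"])
    def test_bit_identical_reproducibility(self, variant, tiny_dataset, small_config):
        a = run_optimizer(tiny_dataset, small_config, variant)
        b = run_optimizer(tiny_dataset, small_config, variant)
        np.testing.assert_array_equal(a.gbest_position, b.gbest_position)
        assert a.gbest_fitness == b.gbest_fitness
        assert [dataclasses.astuple(r) for r in a.trajectory] == [
            dataclasses.astuple(r) for r in b.trajectory
        ]

    @pytest.mark.parametrize("variant", ["bpso", "epso"])
    def test_gbest_fitness_never_decreases(self, variant, tiny_dataset, small_config):
        result = run_optimizer(tiny_dataset, small_config, variant)
        fits = [r.gbest_fitness for r in result.trajectory]
        assert all(a <= b for a, b in zip(fits, fits[1:]))
        assert result.gbest_fitness == fits[-1]
        assert len(result.trajectory) == small_config.max_iter

    def test_trajectory_file_columns(self, tiny_dataset, small_config, tmp_path):
        result = run_optimizer(tiny_dataset, small_config, "epso")
        path = tmp_path / "traj.tsv"
        result.write_trajectory(path)
        header = path.read_text().splitlines()[0].split("\t")
        assert header == ["iteration", "w", "gbest_fitness", "gbest_accuracy",
                          "gbest_num_genes"]

    def test_unknown_variant_rejected(self, tiny_dataset, small_config):
        with pytest.raises(ValueError):
            run_optimizer(tiny_dataset, small_config, "cuckoo")
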