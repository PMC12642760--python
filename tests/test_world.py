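"""Arena dynamics: kinematics, food, bites, scenarios, conservation."""

import math

import numpy as np
import pytest

from efish.config import ArenaConfig
from efish.rng import substream
from efish.world import (Action, World, make_scenario, move_agent,
                         resolve_bites, update_food)


def _logistic(x):
    return 1.0 / (1.0 + math.exp(-x))


class TestReset:
    def test_determinism(self, small_arena):
        a = World(small_arena, seed=9)
        b = World(small_arena, seed=9)
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.headings, b.headings)
        np.testing.assert_array_equal(a.food.item_positions, b.food.item_positions)
        np.testing.assert_array_equal(a.dominance, b.dominance)

    def test_counts_and_bounds(self, small_arena):
        w = World(small_arena, seed=1)
        assert w.positions.shape == (3, 2)
        assert len(w.food.patch_centers) == 2
        assert np.all(w.positions >= 0)
        assert np.all(w.positions[:, 0] <= small_arena.width_cm)
        assert np.all(w.positions[:, 1] <= small_arena.height_cm)
        # items within their patch disc, patches fully inside the arena
        for pos, patch in zip(w.food.item_positions, w.food.item_patch):
            d = np.linalg.norm(pos - w.food.patch_centers[patch])
            assert d <= small_arena.patch_radius_cm + 1e-12

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            ArenaConfig(width_cm=10.0, height_cm=10.0, patch_radius_cm=8.0)

    def test_two_fish_placement(self):
        cfg = make_scenario("two_fish")
        for seed in range(20):
            w = World(cfg, seed=seed)
            patch = w.food.patch_centers[0]
            assert np.linalg.norm(w.positions[0] - patch) <= cfg.patch_radius_cm
            assert (np.linalg.norm(w.positions[0] - w.positions[1])
                    <= cfg.comm_radius_cm)


class TestMoveAgent:
    def test_zero_input_no_motion(self, small_arena):
        p, h, s = move_agent(np.array([10.0, 10.0]), 1.0, Action(), small_arena)
        np.testing.assert_array_equal(p, [10.0, 10.0])
        assert h == 1.0 and s == 0.0

    def test_turn_wraps_full_circle(self, small_arena):
        cfg = small_arena
        steps = math.ceil(2 * math.pi / (cfg.omega_max_rad_s * cfg.dt_s))
        h = 0.3
        for _ in range(steps):
            _, h, _ = move_agent(np.array([50.0, 40.0]), h,
                                 Action(turn=1.0), cfg)
        per_step = cfg.omega_max_rad_s * cfg.dt_s
        assert min(abs(h - 0.3), 2 * math.pi - abs(h - 0.3)) <= per_step + 1e-9

    def test_wall_collision_matches_substep_oracle(self, small_arena):
        # straight-line motion into a wall: clamping equals fine-grained
        # integration with the normal velocity zeroed on contact
        cfg = small_arena
        pos = np.array([1.0, 40.0])
        heading = math.pi * 0.9           # mostly -x, slightly +y
        a = Action(thrust=1.0, turn=0.0)
        new, h, _ = move_agent(pos, heading, a, cfg)

        n_sub = 1000
        p = pos.copy()
        hh = heading  # turn is zero so heading fixed after (no-op) update
        v = cfg.v_max_cm_s * np.array([math.cos(hh), math.sin(hh)])
        for _ in range(n_sub):
            step = v * cfg.dt_s / n_sub
            cand = p + step
            if cand[0] < 0 or cand[0] > cfg.width_cm:
                cand[0] = min(max(cand[0], 0.0), cfg.width_cm)
            if cand[1] < 0 or cand[1] > cfg.height_cm:
                cand[1] = min(max(cand[1], 0.0), cfg.height_cm)
            p = cand
        np.testing.assert_allclose(new, p, atol=1e-9)
        assert 0.0 <= new[0] <= cfg.width_cm


class TestUpdateFood:
    def test_zero_rate_unchanged(self, small_arena):
        cfg = small_arena.replace(replenish_rate_per_s=0.0)
        w = World(cfg, seed=0)
        before = w.food.item_positions.copy()
        after = update_food(w.food, cfg, substream(0, "x"))
        np.testing.assert_array_equal(after.item_positions, before)

    def test_at_capacity_no_spawn(self, small_arena):
        cfg = small_arena.replace(replenish_rate_per_s=1e6)
        w = World(cfg, seed=0)   # starts at capacity
        after = update_food(w.food, cfg, substream(0, "x"))
        assert len(after.item_positions) == len(w.food.item_positions)

    def test_replenishment_rate_monte_carlo(self):
        # mean items after T steps from empty matches an independently coded
        # Bernoulli-sum oracle within 3 SE over 1000 trials
        cfg = ArenaConfig(n_patches=1, patch_capacity=10,
                          replenish_rate_per_s=2.0, dt_s=0.04, n_agents=1)
        p_gain = min(1.0, cfg.replenish_rate_per_s * cfg.dt_s)
        T, trials = 40, 1000
        counts = np.zeros(trials)
        for k in range(trials):
            w = World(cfg, seed=k)
            food = w.food
            # empty the patch
            from efish.world import FoodState
            food = FoodState(food.patch_centers, np.zeros((0, 2)),
                             np.zeros(0, int), np.zeros((0, 2)))
            rng = substream(k, "mc")
            for _ in range(T):
                food = update_food(food, cfg, rng)
            counts[k] = len(food.item_positions)

        # oracle: capped Bernoulli sum, same cap dynamics
        orng = np.random.default_rng(999)
        oracle = np.zeros(100_000)
        for k in range(len(oracle)):
            c = 0
            for _ in range(T):
                if c < cfg.patch_capacity and orng.uniform() < p_gain:
                    c += 1
            oracle[k] = c
        se = counts.std(ddof=1) / math.sqrt(trials)
        assert abs(counts.mean() - oracle.mean()) < 3 * se


class TestResolveBites:
    def _geom(self, cfg, d_biter, d_victim):
        positions = np.array([[50.0, 40.0], [52.0, 40.0], [10.0, 10.0]])
        headings = np.array([0.0, math.pi, 0.0])   # 0 faces 1 and vice versa
        dom = np.array([d_biter, d_victim, 0.5])
        return positions, headings, dom

    def test_no_bites_no_deltas(self, small_arena):
        pos, hd, dom = self._geom(small_arena, 0.7, 0.3)
        acts = [Action(), Action(), Action()]
        deltas = resolve_bites(pos, hd, dom, acts, small_arena)
        assert np.all(deltas == 0.0)

    def test_equal_dominance_split(self, small_arena):
        pos, hd, dom = self._geom(small_arena, 0.5, 0.5)
        acts = [Action(bite=1), Action(), Action()]
        deltas = resolve_bites(pos, hd, dom, acts, small_arena)
        assert deltas[0] == pytest.approx(-small_arena.c_bite / 2)
        assert deltas[1] == pytest.approx(-small_arena.c_bite / 2)

    @pytest.mark.parametrize("diff", [-1.0, -0.5, 0.0, 0.5, 1.0])
    def test_logistic_table(self, small_arena, diff):
        d_b = 0.5 + diff / 2
        d_v = 0.5 - diff / 2
        pos, hd, dom = self._geom(small_arena, d_b, d_v)
        acts = [Action(bite=1), Action(), Action()]
        deltas = resolve_bites(pos, hd, dom, acts, small_arena)
        k, c = small_arena.bite_k, small_arena.c_bite
        assert deltas[1] == pytest.approx(-c * _logistic(k * (d_b - d_v)))
        assert deltas[0] == pytest.approx(-c * _logistic(k * (d_v - d_b)))
        # the more dominant party always loses less
        if diff > 0:
            assert deltas[0] > deltas[1]
        elif diff < 0:
            assert deltas[0] < deltas[1]

    def test_frontal_halfplane_required(self, small_arena):
        pos = np.array([[50.0, 40.0], [47.0, 40.0], [10.0, 10.0]])
        hd = np.array([0.0, math.pi, 0.0])   # victim is behind the biter
        dom = np.array([0.5, 0.5, 0.5])
        deltas = resolve_bites(pos, hd, dom, [Action(bite=1), Action(), Action()],
                               small_arena)
        assert np.all(deltas == 0.0)


class TestStep:
    def test_action_count_mismatch(self, small_arena):
        w = World(small_arena, seed=0)
        with pytest.raises(ValueError):
            w.step([Action(), Action()])

    def test_static_world_zero_actions(self, small_arena):
        cfg = small_arena.replace(replenish_rate_per_s=0.0)
        w = World(cfg, seed=11)
        w.positions[:] = [[50, 40], [60, 40], [70, 40]]  # away from food
        pos = w.positions.copy()
        rewards, done = w.step([Action(), Action(), Action()])
        np.testing.assert_array_equal(w.positions, pos)
        assert np.all(rewards == 0.0) and not done

    def test_eating_rule(self, small_arena):
        w = World(small_arena, seed=2)
        w.positions[0] = w.food.item_positions[0] + [0.5, 0.0]
        rewards, _ = w.step([Action(), Action(), Action()])
        assert w.food_eaten[0] >= 1
        assert rewards[0] >= small_arena.r_food - 1e-12

    def test_eod_cost(self, small_arena):
        cfg = small_arena.replace(replenish_rate_per_s=0.0)
        w = World(cfg, seed=11)
        w.positions[:] = [[50, 40], [60, 40], [70, 40]]
        rewards, _ = w.step([Action(eod=1), Action(), Action()])
        assert rewards[0] == pytest.approx(-cfg.c_eod)

    def test_rollout_matches_subupdate_oracle(self, small_arena):
        # step() equals an independent composition of the tested sub-updates
        # (move -> replenish -> bites -> eat -> EOD cost), sharing RNG state
        cfg = small_arena
        w = World(cfg, seed=33)
        oracle = World(cfg, seed=33)
        arng = np.random.default_rng(5)
        for _ in range(100):
            acts = np.column_stack([arng.uniform(0, 1, 3),
                                    arng.uniform(-1, 1, 3),
                                    arng.integers(0, 2, 3),
                                    arng.integers(0, 2, 3)]).astype(float)
            w.step(acts)

            alist = [Action(*row).clipped() for row in acts]
            for i, a in enumerate(alist):
                (oracle.positions[i], oracle.headings[i],
                 oracle.speeds[i]) = move_agent(oracle.positions[i],
                                                oracle.headings[i], a, cfg)
                oracle.eod[i] = bool(a.eod)
            oracle.food = update_food(oracle.food, cfg, oracle._food_rng)
            bite_d = resolve_bites(oracle.positions, oracle.headings,
                                   oracle.dominance, alist, cfg)
            eat_d = np.zeros(3)
            items = oracle.food.item_positions
            if len(items):
                d = np.linalg.norm(items[:, None, :]
                                   - oracle.positions[None, :, :], axis=-1)
                nearest = d.argmin(axis=1)
                keep = np.ones(len(items), bool)
                for m in range(len(items)):
                    if d[m, nearest[m]] <= cfg.eat_radius_cm:
                        eat_d[nearest[m]] += cfg.r_food
                        keep[m] = False
                from efish.world import FoodState
                oracle.food = FoodState(oracle.food.patch_centers, items[keep],
                                        oracle.food.item_patch[keep],
                                        oracle.food.item_moments[keep])
            np.testing.assert_array_equal(w.positions, oracle.positions)
            np.testing.assert_array_equal(w.headings, oracle.headings)
            np.testing.assert_array_equal(w.food.item_positions,
                                          oracle.food.item_positions)

    def test_containment_and_monotone_food(self, small_arena):
        w = World(small_arena, seed=8)
        arng = np.random.default_rng(0)
        prev_eaten = w.food_eaten.copy()
        for _ in range(150):
            acts = np.column_stack([np.ones(3), arng.uniform(-1, 1, 3),
                                    np.zeros(3), np.zeros(3)])
            w.step(acts)
            assert np.all(w.positions[:, 0] >= 0)
            assert np.all(w.positions[:, 0] <= small_arena.width_cm)
            assert np.all(w.positions[:, 1] >= 0)
            assert np.all(w.positions[:, 1] <= small_arena.height_cm)
            assert np.all(w.headings >= 0) and np.all(w.headings < 2 * np.pi)
            assert np.all(w.food_eaten >= prev_eaten)
            prev_eaten = w.food_eaten.copy()

    def test_item_conservation_competitive(self, small_arena):
        w = World(small_arena, seed=21)
        arng = np.random.default_rng(1)
        for _ in range(200):
            acts = np.column_stack([arng.uniform(0, 1, 3),
                                    arng.uniform(-1, 1, 3),
                                    np.zeros(3), np.zeros(3)])
            w.step(acts)
        assert (w.items_consumed + len(w.food.item_positions)
                == w.items_spawned)
        assert w.items_consumed == w.food_eaten.sum()

    def test_zero_sum_scarcity(self):
        cfg = ArenaConfig(n_agents=4, n_patches=2, patch_capacity=3,
                          replenish_rate_per_s=0.0, max_steps=400, seed=0)
        w = World(cfg, seed=0)
        initial = len(w.food.item_positions)
        arng = np.random.default_rng(2)
        for _ in range(400):
            acts = np.column_stack([np.ones(4), arng.uniform(-1, 1, 4),
                                    np.zeros(4), np.zeros(4)])
            _, done = w.step(acts)
            if done:
                break
        assert w.food_eaten.sum() <= initial

    def test_episode_terminates_at_max_steps(self, small_arena):
        cfg = small_arena.replace(max_steps=5)
        w = World(cfg, seed=0)
        done = False
        for _ in range(5):
            _, done = w.step([Action()] * 3)
        assert done
        with pytest.raises(RuntimeError):
            w.step([Action()] * 3)


class TestScenarios:
    def test_noncompetitive_definition(self):
        cfg = make_scenario("noncompetitive")
        assert cfg.competition is False

    def test_two_fish_preset(self):
        cfg = make_scenario("two_fish")
        assert cfg.n_agents == 2 and cfg.n_patches == 1
        assert cfg.competition is False

    def test_override_semantics(self):
        cfg = make_scenario("competitive", knollenorgan_enabled=False)
        assert cfg.knollenorgan_enabled is False
        assert cfg.competition is True

    def test_unknown_preset(self):
        with pytest.raises(ValueError):
            make_scenario("aquarium")

    def test_noncompetitive_instant_refill(self):
        cfg = make_scenario("noncompetitive", n_agents=1, n_patches=1)
        w = World(cfg, seed=3)
        w.positions[0] = w.food.item_positions[0]
        w.step(np.zeros((1, 4)))
        assert w.food_eaten[0] >= 1
        # replenishment precedes eating within a step, so the patch is back
        # at capacity after the next step (agent moved away)
        w.positions[0] = [5.0, 5.0]
        w.step(np.zeros((1, 4)))
        assert len(w.food.item_positions) == cfg.patch_capacity
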