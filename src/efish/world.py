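"""Discrete-time 2D foraging arena.

Agents are point fish with a heading; per step they choose forward thrust,
turning, a binary electric organ discharge (EOD) and a bite.  Food comes in
circular patches that replenish stochastically (competitive mode) or are
topped up to capacity every step (non-competitive mode).  Eating is automatic
on proximity.  Bites land on a conspecific in the frontal half-plane within
``bite_radius_cm`` and cost both parties, with the penalty split by a
logistic of the dominance difference: the more dominant party loses less.

Step order: move -> replenish food -> resolve bites -> eat -> EOD cost.
All randomness derives from named substreams of the reset seed, so a
(config, seed) pair replays bit-exactly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Union

import numpy as np

from .config import ArenaConfig
from .rng import substream

__all__ = ["AgentState", "Action", "FoodState", "World",
           "move_agent", "update_food", "resolve_bites", "make_scenario",
           "SCENARIO_PRESETS"]

TWO_PI = 2.0 * math.pi


@dataclass
class AgentState:
    agent_id: int
    position: np.ndarray          # (2,) cm
    heading: float                # rad, CCW from +x, in [0, 2pi)
    speed: float                  # cm/s over the last step
    dominance: float              # fixed per episode, in [0,1]
    eod_emitted: bool
    food_eaten: int
    cumulative_reward: float
    hidden_state_ref: object = None


@dataclass
class Action:
    thrust: float = 0.0           # [0,1]
    turn: float = 0.0             # [-1,1]
    eod: int = 0
    bite: int = 0

    def clipped(self) -> "Action":
        return Action(float(np.clip(self.thrust, 0.0, 1.0)),
                      float(np.clip(self.turn, -1.0, 1.0)),
                      int(round(np.clip(self.eod, 0, 1))),
                      int(round(np.clip(self.bite, 0, 1))))

    def as_array(self) -> np.ndarray:
        return np.array([self.thrust, self.turn, self.eod, self.bite], dtype=float)


@dataclass
class FoodState:
    patch_centers: np.ndarray          # (P,2)
    item_positions: np.ndarray         # (M,2)
    item_patch: np.ndarray             # (M,) patch index of each item
    item_moments: np.ndarray           # (M,2) static dipole carried by each item

    @property
    def items_remaining_per_patch(self) -> np.ndarray:
        n_patches = len(self.patch_centers)
        return np.bincount(self.item_patch, minlength=n_patches)[:n_patches]


def _wrap_angle(a: float) -> float:
    return a % TWO_PI


def move_agent(position: np.ndarray, heading: float, action: Action,
               config: ArenaConfig) -> tuple:
    """Kinematic update for one agent; returns (position, heading, speed).

    Heading turns first, then the agent translates along the new heading.
    The position is clamped per-axis to the arena; for straight-line motion
    within a step this equals sliding along the wall with the normal velocity
    zeroed.
    """
    a = action.clipped()
    heading = _wrap_angle(heading + a.turn * config.omega_max_rad_s * config.dt_s)
    step_len = a.thrust * config.v_max_cm_s * config.dt_s
    new = position + step_len * np.array([math.cos(heading), math.sin(heading)])
    clamped = np.array([min(max(new[0], 0.0), config.width_cm),
                        min(max(new[1], 0.0), config.height_cm)])
    speed = float(np.linalg.norm(clamped - position)) / config.dt_s
    return clamped, heading, speed


def _spawn_item(center: np.ndarray, radius: float, rng: np.random.Generator,
                moment_scale: float) -> tuple:
    """Uniform position in the patch disc + a random static dipole."""
    r = radius * math.sqrt(rng.uniform())
    th = rng.uniform(0.0, TWO_PI)
    pos = center + r * np.array([math.cos(th), math.sin(th)])
    phi = rng.uniform(0.0, TWO_PI)
    mom = moment_scale * np.array([math.cos(phi), math.sin(phi)])
    return pos, mom


def update_food(food: FoodState, config: ArenaConfig, rng: np.random.Generator) -> FoodState:
    """Stochastic replenishment (competitive) or instant refill (non-competitive).

    Each patch below capacity gains one item with probability
    min(1, replenish_rate_per_s * dt_s), at a uniform position in the disc.
    With competition off, every patch is refilled to capacity immediately.
    """
    counts = food.items_remaining_per_patch
    new_pos, new_patch, new_mom = [], [], []
    if config.competition:
        p_gain = min(1.0, config.replenish_rate_per_s * config.dt_s)
        for i, c in enumerate(counts):
            if c < config.patch_capacity and rng.uniform() < p_gain:
                pos, mom = _spawn_item(food.patch_centers[i], config.patch_radius_cm,
                                       rng, config.passive_moment)
                new_pos.append(pos); new_patch.append(i); new_mom.append(mom)
    else:
        for i, c in enumerate(counts):
            for _ in range(config.patch_capacity - int(c)):
                pos, mom = _spawn_item(food.patch_centers[i], config.patch_radius_cm,
                                       rng, config.passive_moment)
                new_pos.append(pos); new_patch.append(i); new_mom.append(mom)
    if not new_pos:
        return food
    return FoodState(
        patch_centers=food.patch_centers,
        item_positions=np.vstack([food.item_positions.reshape(-1, 2), np.array(new_pos)]),
        item_patch=np.concatenate([food.item_patch, np.array(new_patch, dtype=int)]),
        item_moments=np.vstack([food.item_moments.reshape(-1, 2), np.array(new_mom)]),
    )


def _logistic(x: float) -> float:
    return 1.0 / (1.0 + math.exp(-x))


def resolve_bites(positions: np.ndarray, headings: np.ndarray,
                  dominance: np.ndarray, actions: Sequence[Action],
                  config: ArenaConfig) -> np.ndarray:
    """Per-agent reward deltas from bites.

    A bite lands iff the biter's bite flag is set and some conspecific lies
    within ``bite_radius_cm`` in the frontal half-plane (nearest such
    conspecific is the victim).  With biter dominance d_b and victim d_v:

        victim delta = -c_bite * sigma(k (d_b - d_v))
        biter  delta = -c_bite * sigma(k (d_v - d_b))

    so at equal dominance each loses c_bite/2 and the more dominant party in
    the encounter always loses less.
    """
    n = len(positions)
    deltas = np.zeros(n)
    for b in range(n):
        if not actions[b].bite:
            continue
        fwd = np.array([math.cos(headings[b]), math.sin(headings[b])])
        best, best_d = None, np.inf
        for v in range(n):
            if v == b:
                continue
            rel = positions[v] - positions[b]
            d = float(np.linalg.norm(rel))
            if d <= config.bite_radius_cm and float(rel @ fwd) > 0.0 and d < best_d:
                best, best_d = v, d
        if best is None:
            continue
        diff = config.bite_k * (dominance[b] - dominance[best])
        deltas[best] -= config.c_bite * _logistic(diff)
        deltas[b] -= config.c_bite * _logistic(-diff)
    return deltas


class World:
    """Mutable arena state; ``reset`` and ``step`` are the lifecycle API."""

    def __init__(self, config: ArenaConfig, seed: Optional[int] = None):
        self.config = config
        self.reset(seed if seed is not None else config.seed)

    # -- lifecycle ---------------------------------------------------------

    def reset(self, seed: int) -> "World":
        cfg = self.config
        self.seed = int(seed)
        init = substream(seed, "world-init")
        self._food_rng = substream(seed, "food")
        w, h, pr = cfg.width_cm, cfg.height_cm, cfg.patch_radius_cm
        if cfg.scenario == "two_fish":
            centers = np.array([[w / 2.0, h / 2.0]])[: cfg.n_patches]
        else:
            centers = np.column_stack([init.uniform(pr, w - pr, cfg.n_patches),
                                       init.uniform(pr, h - pr, cfg.n_patches)])
        pos, mom, patch = [], [], []
        for i in range(cfg.n_patches):
            for _ in range(cfg.patch_capacity):
                p, m = _spawn_item(centers[i], pr, init, cfg.passive_moment)
                pos.append(p); mom.append(m); patch.append(i)
        self.food = FoodState(centers,
                              np.array(pos).reshape(-1, 2),
                              np.array(patch, dtype=int),
                              np.array(mom).reshape(-1, 2))
        self.positions = np.column_stack([init.uniform(0, w, cfg.n_agents),
                                          init.uniform(0, h, cfg.n_agents)])
        self.headings = init.uniform(0.0, TWO_PI, cfg.n_agents)
        self.dominance = init.uniform(0.0, 1.0, cfg.n_agents)
        if cfg.scenario == "two_fish":
            # A (agent 0) starts inside the patch; B within communication radius of A.
            r = pr * math.sqrt(init.uniform()); th = init.uniform(0, TWO_PI)
            self.positions[0] = centers[0] + r * np.array([math.cos(th), math.sin(th)])
            while True:
                r = cfg.comm_radius_cm * math.sqrt(init.uniform())
                th = init.uniform(0, TWO_PI)
                cand = self.positions[0] + r * np.array([math.cos(th), math.sin(th)])
                if 0 <= cand[0] <= w and 0 <= cand[1] <= h:
                    self.positions[1] = cand
                    break
        self.speeds = np.zeros(cfg.n_agents)
        self.last_turn = np.zeros(cfg.n_agents)
        self.eod = np.zeros(cfg.n_agents, dtype=bool)
        self.food_eaten = np.zeros(cfg.n_agents, dtype=int)
        self.cumulative_reward = np.zeros(cfg.n_agents)
        self.step_count = 0
        self.done = False
        # spawn/consumption ledger (conservation checks)
        self.items_spawned = int(len(self.food.item_positions))
        self.items_consumed = 0
        return self

    # -- per-step update ---------------------------------------------------

    def step(self, actions: Union[Sequence[Action], np.ndarray]):
        """Advance one timestep; returns (rewards, done)."""
        cfg = self.config
        if self.done:
            raise RuntimeError("episode finished; call reset()")
        acts = self._coerce_actions(actions)
        rewards = np.zeros(cfg.n_agents)

        for i, a in enumerate(acts):
            self.positions[i], self.headings[i], self.speeds[i] = move_agent(
                self.positions[i], self.headings[i], a, cfg)
            self.last_turn[i] = a.turn
            self.eod[i] = bool(a.eod)

        n_before = len(self.food.item_positions)
        self.food = update_food(self.food, cfg, self._food_rng)
        self.items_spawned += len(self.food.item_positions) - n_before

        rewards += resolve_bites(self.positions, self.headings, self.dominance,
                                 acts, cfg)
        rewards += self._eat()
        rewards -= cfg.c_eod * self.eod.astype(float)

        self.cumulative_reward += rewards
        self.step_count += 1
        self.done = self.step_count >= cfg.max_steps
        return rewards, self.done

    def _coerce_actions(self, actions) -> List[Action]:
        if isinstance(actions, np.ndarray):
            if actions.shape != (self.config.n_agents, 4):
                raise ValueError(f"expected ({self.config.n_agents}, 4) action array")
            return [Action(*row).clipped() for row in actions]
        acts = [a.clipped() for a in actions]
        if len(acts) != self.config.n_agents:
            raise ValueError("one action per agent required")
        return acts

    def _eat(self) -> np.ndarray:
        """Consume every item within eat radius of its nearest in-range agent."""
        cfg = self.config
        rewards = np.zeros(cfg.n_agents)
        items = self.food.item_positions
        if len(items) == 0:
            return rewards
        d = np.linalg.norm(items[:, None, :] - self.positions[None, :, :], axis=-1)
        nearest = np.argmin(d, axis=1)
        in_range = d[np.arange(len(items)), nearest] <= cfg.eat_radius_cm
        if in_range.any():
            eaten_by = nearest[in_range]
            for a in eaten_by:
                rewards[a] += cfg.r_food
                self.food_eaten[a] += 1
            self.items_consumed += int(in_range.sum())
            keep = ~in_range
            self.food = FoodState(self.food.patch_centers, items[keep],
                                  self.food.item_patch[keep],
                                  self.food.item_moments[keep])
        return rewards

    # -- views -------------------------------------------------------------

    def agent_state(self, i: int) -> AgentState:
        return AgentState(agent_id=i, position=self.positions[i].copy(),
                          heading=float(self.headings[i]), speed=float(self.speeds[i]),
                          dominance=float(self.dominance[i]),
                          eod_emitted=bool(self.eod[i]),
                          food_eaten=int(self.food_eaten[i]),
                          cumulative_reward=float(self.cumulative_reward[i]))


SCENARIO_PRESETS = {
    "competitive": dict(competition=True, replenish_rate_per_s=0.1),
    "noncompetitive": dict(competition=False),
    "two_fish": dict(scenario="two_fish", n_agents=2, n_patches=1,
                     competition=False, patch_capacity=5),
}


def make_scenario(preset: str, **overrides) -> ArenaConfig:
    """Fully-populated config for one of the named study scenarios.

    ``two_fish`` fixes two agents and a single fully-replenishing central
    patch; at reset, agent A is placed inside the patch and agent B within
    ``comm_radius_cm`` of A.
    """
    if preset not in SCENARIO_PRESETS:
        raise ValueError(f"unknown preset {preset!r}; choose from {sorted(SCENARIO_PRESETS)}")
    kw = dict(SCENARIO_PRESETS[preset])
    kw.update(overrides)
    return ArenaConfig(**kw)
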