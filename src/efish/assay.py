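"""Minimal two-fish social foraging assay.

Agent A sits inside a fully-replenishing food patch; agent B starts at a
random point within communication radius of A.  Across dominance pairings
and ablations (A removed; Knollenorgan disabled) the assay measures how
often B reaches the patch and how much it eats — isolating whether the
long-range social channel carries usable spatial information.

Scripted controllers let the assay run without any training: A discharges
periodically in place; B either climbs its strongest Knollenorgan bin
(falling back to a random walk while it has heard nothing) or random-walks.
A trained shared policy can be substituted for both agents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .config import ArenaConfig
from .policy import ActionDistribution, PolicyState, forward_np, sample_action
from .rng import child_seed, substream
from .sensors import assemble_observation, knollenorgan_channels
from .world import World, make_scenario

__all__ = ["ScriptedEmitter", "KnollenorganClimber", "RandomWalker",
           "run_two_fish_episode", "two_fish_assay", "paired_sign_test"]

TWO_PI = 2.0 * math.pi


class ScriptedEmitter:
    """Stationary agent discharging every ``period`` steps."""

    def __init__(self, period: int = 5):
        self.period = period

    def __call__(self, world: World, idx: int, t: int,
                 rng: np.random.Generator) -> np.ndarray:
        return np.array([0.0, 0.0, float(t % self.period == 0), 0.0])


class RandomWalker:
    """Smooth random walk: moderate thrust, jittered turning, silent."""

    def __call__(self, world: World, idx: int, t: int,
                 rng: np.random.Generator) -> np.ndarray:
        return np.array([0.7, rng.uniform(-0.5, 0.5), 0.0, 0.0])


class KnollenorganClimber:
    """Turns toward the strongest Knollenorgan bin and swims forward.

    Between conspecific pulses it holds course, spreading a large commanded
    turn over several steps (the turn rate saturates at omega_max).  Before
    the first detected pulse it behaves like :class:`RandomWalker`.
    """

    def __init__(self):
        self.pending_turn = 0.0
        self.heard = False

    def __call__(self, world: World, idx: int, t: int,
                 rng: np.random.Generator) -> np.ndarray:
        cfg = world.config
        kn = knollenorgan_channels(world, idx)
        if kn.any():
            b = int(np.argmax(kn))
            center = (b + 0.5) * TWO_PI / cfg.n_bins
            self.pending_turn = (center + math.pi) % TWO_PI - math.pi
            self.heard = True
        if not self.heard:
            return RandomWalker()(world, idx, t, rng)
        max_step = cfg.omega_max_rad_s * cfg.dt_s
        turn = float(np.clip(self.pending_turn / max_step, -1.0, 1.0))
        self.pending_turn -= turn * max_step
        return np.array([1.0, turn, 0.0, 0.0])


def run_two_fish_episode(config: ArenaConfig, seed: int,
                         policy_a=None, policy_b=None,
                         shared_policy: Optional[PolicyState] = None,
                         dominance: Optional[Tuple[float, float]] = None,
                         a_present: bool = True,
                         max_steps: Optional[int] = None) -> dict:
    """One assay episode; returns reach/consumption outcomes for B.

    ``policy_a``/``policy_b`` are scripted controller instances (fresh per
    episode); ``shared_policy`` runs the trained controller for both agents
    instead.  With ``a_present=False``, agent A is withdrawn entirely: the
    episode runs in a single-agent world holding only B, with the same food
    state and the same B start pose drawn for the paired seed.
    """
    steps = max_steps if max_steps is not None else config.max_steps
    world = World(config, seed=seed)
    if dominance is not None:
        world.dominance = np.array(dominance, float)
    patch_center = world.food.patch_centers[0]
    b_start = world.positions[1].copy()

    if not a_present:
        solo = config.replace(n_agents=1, scenario="default")
        solo_world = World(solo, seed=seed)
        solo_world.food = world.food
        solo_world.positions[0] = b_start
        solo_world.headings[0] = world.headings[1]
        solo_world.dominance[0] = world.dominance[1]
        world = solo_world
        b_idx = 0
    else:
        b_idx = 1

    rng = substream(seed, "assay-actions")
    hidden = (np.zeros((config.n_agents, shared_policy.config.rnn_width))
              if shared_policy else None)
    reached = False
    for t in range(steps):
        n = world.config.n_agents
        if shared_policy is not None:
            obs = np.array([assemble_observation(world, i) for i in range(n)])
            raw, _, hidden_new = forward_np(shared_policy.params,
                                            shared_policy.config, obs,
                                            hidden[:n])
            actions, _ = sample_action(ActionDistribution(raw), rng)
            hidden[:n] = hidden_new
        else:
            rows = []
            for i in range(n):
                ctl = policy_b if i == b_idx else policy_a
                rows.append(ctl(world, i, t, rng) if ctl is not None
                            else np.zeros(4))
            actions = np.array(rows)
        world.step(actions)
        if np.linalg.norm(world.positions[b_idx] - patch_center) \
                <= world.config.patch_radius_cm:
            reached = True

    rel = b_start - patch_center
    return {"reached": reached,
            "food_b": int(world.food_eaten[b_idx]),
            "start_distance_cm": float(np.linalg.norm(rel)),
            "start_bearing_rad": float(math.atan2(rel[1], rel[0]) % TWO_PI)}


def two_fish_assay(dominance_pairs: Sequence[Tuple[float, float]],
                   n_runs: int = 100, seed: int = 0,
                   conditions: Sequence[str] = ("baseline", "a_removed",
                                                "knollenorgan_off"),
                   shared_policy: Optional[PolicyState] = None,
                   scripted_a_period: int = 5,
                   max_steps: int = 250,
                   config_overrides: Optional[dict] = None,
                   n_bearing_bins: int = 4) -> pd.DataFrame:
    """Full assay grid: (dominance pair) x (condition), ``n_runs`` episodes each.

    Episode seeds are shared across conditions (paired design).  Without a
    trained ``shared_policy``, A is a periodic scripted emitter and B a
    Knollenorgan climber.  Returns one row per condition with B's
    patch-reach rate, mean food eaten, and reach rates binned by B's start
    bearing and distance.
    """
    overrides = dict(config_overrides or {})
    rows = []
    for (dom_a, dom_b) in dominance_pairs:
        for cond in conditions:
            cfg = make_scenario("two_fish",
                                knollenorgan_enabled=(cond != "knollenorgan_off"),
                                **overrides)
            per_run = []
            for r in range(n_runs):
                ep_seed = child_seed(seed, "assay-episode", r)
                res = run_two_fish_episode(
                    cfg, ep_seed,
                    policy_a=None if shared_policy else ScriptedEmitter(scripted_a_period),
                    policy_b=None if shared_policy else KnollenorganClimber(),
                    shared_policy=shared_policy,
                    dominance=(dom_a, dom_b),
                    a_present=(cond != "a_removed"),
                    max_steps=max_steps)
                per_run.append(res)
            reach = np.array([r["reached"] for r in per_run])
            dist = np.array([r["start_distance_cm"] for r in per_run])
            bear = np.array([r["start_bearing_rad"] for r in per_run])
            row = {"dom_a": dom_a, "dom_b": dom_b, "condition": cond,
                   "n_runs": n_runs,
                   "reach_rate": float(reach.mean()),
                   "mean_food_b": float(np.mean([r["food_b"] for r in per_run])),
                   "median_start_distance_cm": float(np.median(dist))}
            for k in range(n_bearing_bins):
                in_bin = (bear // (TWO_PI / n_bearing_bins)).astype(int) == k
                row[f"reach_rate_bearing_bin{k}"] = \
                    float(reach[in_bin].mean()) if in_bin.any() else np.nan
            near = dist <= np.median(dist)
            row["reach_rate_near_start"] = float(reach[near].mean())
            row["reach_rate_far_start"] = float(reach[~near].mean()) if (~near).any() else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def paired_sign_test(success_a: Sequence[bool], success_b: Sequence[bool]) -> dict:
    """One-sided sign test that paired condition A succeeds more often than B."""
    a = np.asarray(success_a, bool)
    b = np.asarray(success_b, bool)
    if a.shape != b.shape:
        raise ValueError("paired samples must align")
    n_a = int(np.sum(a & ~b))
    n_b = int(np.sum(~a & b))
    n = n_a + n_b
    p = stats.binomtest(n_a, n, 0.5, alternative="greater").pvalue if n else 1.0
    return {"wins_a": n_a, "wins_b": n_b, "n_discordant": n, "p_value": float(p)}
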