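"""Synthetic episode traces with planted, exactly-known structure.

Stands in for trained-agent rollouts when testing analytics: scripted or
stochastic EOD trains (Bernoulli / renewal / literal strings), scripted
trajectories (stationary / straight / waypoints), planted pairwise
interaction windows and planted food-consumption tallies.  The emitted
:class:`~efish.trace.EpisodeTrace` is schema-identical to simulator output,
so every analytics routine runs on it unchanged.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, List, Optional, Sequence, Tuple

import numpy as np

from .config import ArenaConfig
from .rng import substream
from .sensors import block_layout
from .trace import EpisodeTrace

__all__ = ["SyntheticTraceSpec", "generate_synthetic_trace",
           "bernoulli_train", "renewal_train"]


@dataclass
class SyntheticTraceSpec:
    n_agents: int = 2
    n_steps: int = 1000
    dt_s: float = 0.04
    # per-agent EOD process: ("bernoulli", p) | ("scripted", "0101...")
    #                        | ("renewal", sampler(rng) -> interval seconds)
    eod: Optional[List[tuple]] = None
    # per-agent trajectory: ("stationary", (x, y) | None)
    #                       | ("straight", (x0, y0), heading_rad, speed_cm_s)
    #                       | ("waypoints", [(x, y), ...])
    trajectory: Optional[List[tuple]] = None
    # planted close-proximity bouts: (agent_a, agent_b, start, length, distance_cm)
    interaction_windows: List[Tuple[int, int, int, int, float]] = field(default_factory=list)
    # planted final food-consumption tally per agent (accrued linearly)
    consumption: Optional[Sequence[int]] = None
    seed: int = 0


def bernoulli_train(p: float, n_steps: int, rng: np.random.Generator) -> np.ndarray:
    return (rng.uniform(size=n_steps) < p).astype(np.uint8)


def renewal_train(sampler: Callable[[np.random.Generator], float], n_steps: int,
                  dt_s: float, rng: np.random.Generator) -> np.ndarray:
    """Binary train whose inter-pulse intervals are drawn from ``sampler``
    (seconds, quantized to at least one step)."""
    train = np.zeros(n_steps, dtype=np.uint8)
    t = 0
    train[0] = 1
    while True:
        t += max(1, int(round(float(sampler(rng)) / dt_s)))
        if t >= n_steps:
            break
        train[t] = 1
    return train


def _default_slots(n_agents: int, spacing: float = 60.0) -> np.ndarray:
    return np.column_stack([spacing * (np.arange(n_agents) + 1),
                            np.full(n_agents, spacing)])


def _trajectory(spec_entry: tuple, slot: np.ndarray, n_steps: int,
                dt_s: float) -> np.ndarray:
    kind = spec_entry[0]
    if kind == "stationary":
        p = np.asarray(spec_entry[1], float) if spec_entry[1] is not None else slot
        return np.tile(p, (n_steps, 1))
    if kind == "straight":
        p0 = np.asarray(spec_entry[1], float)
        heading, speed = float(spec_entry[2]), float(spec_entry[3])
        direction = np.array([math.cos(heading), math.sin(heading)])
        t = np.arange(n_steps)[:, None]
        return p0 + speed * dt_s * t * direction
    if kind == "waypoints":
        wps = np.asarray(spec_entry[1], float)
        if len(wps) < 2:
            return np.tile(wps[0], (n_steps, 1))
        s = np.linspace(0.0, len(wps) - 1.0, n_steps)
        i = np.minimum(s.astype(int), len(wps) - 2)
        frac = (s - i)[:, None]
        return wps[i] * (1.0 - frac) + wps[i + 1] * frac
    raise ValueError(f"unknown trajectory kind {kind!r}")


def _eod_train(entry: tuple, n_steps: int, dt_s: float,
               rng: np.random.Generator) -> np.ndarray:
    kind = entry[0]
    if kind == "bernoulli":
        return bernoulli_train(float(entry[1]), n_steps, rng)
    if kind == "scripted":
        s = entry[1]
        if len(s) != n_steps:
            raise ValueError(f"scripted EOD string length {len(s)} != n_steps {n_steps}")
        return np.array([int(c) for c in s], dtype=np.uint8)
    if kind == "renewal":
        return renewal_train(entry[1], n_steps, dt_s, rng)
    raise ValueError(f"unknown EOD process {kind!r}")


def generate_synthetic_trace(spec: SyntheticTraceSpec) -> EpisodeTrace:
    """Materialize the spec into a trace; planted structure is exact."""
    n, T = spec.n_agents, spec.n_steps
    if n < 1 or T < 1:
        raise ValueError("need n_agents >= 1 and n_steps >= 1")
    for (a, b, start, length, dist) in spec.interaction_windows:
        if not (0 <= a < n and 0 <= b < n and a != b):
            raise ValueError(f"bad interaction pair ({a}, {b})")
        if start < 0 or start + length > T:
            raise ValueError("interaction window outside the episode")
    if spec.consumption is not None and len(spec.consumption) != n:
        raise ValueError("consumption vector length != n_agents")

    rng = substream(spec.seed, "synthetic-trace")
    slots = _default_slots(n)
    traj_spec = spec.trajectory or [("stationary", None)] * n
    eod_spec = spec.eod or [("bernoulli", 0.1)] * n
    if len(traj_spec) != n or len(eod_spec) != n:
        raise ValueError("need one trajectory and one EOD process per agent")

    positions = np.stack([_trajectory(traj_spec[i], slots[i], T, spec.dt_s)
                          for i in range(n)], axis=1)   # (T, N, 2)
    for (a, b, start, length, dist) in spec.interaction_windows:
        sl = slice(start, start + length)
        positions[sl, b] = positions[sl, a] + np.array([dist, 0.0])

    eod = np.stack([_eod_train(eod_spec[i], T, spec.dt_s,
                               substream(spec.seed, "synthetic-eod", i))
                    for i in range(n)], axis=1)          # (T, N)

    deltas = np.diff(positions, axis=0, prepend=positions[:1])
    speeds = np.linalg.norm(deltas, axis=-1) / spec.dt_s
    headings = np.where(speeds > 0, np.arctan2(deltas[..., 1], deltas[..., 0]),
                        0.0) % (2 * math.pi)

    if spec.consumption is not None:
        c = np.asarray(spec.consumption, dtype=int)
        ramp = np.arange(1, T + 1)[:, None] / T
        food_eaten = np.floor(ramp * c[None, :]).astype(int)
    else:
        food_eaten = np.zeros((T, n), dtype=int)

    extent = float(max(positions[..., 0].max(), positions[..., 1].max()) + 60.0)
    cfg = ArenaConfig(width_cm=extent, height_cm=extent, dt_s=spec.dt_s,
                      max_steps=T, n_agents=n, n_patches=0, seed=spec.seed)
    r_food, c_eod = cfg.r_food, cfg.c_eod
    eaten_step = np.diff(food_eaten, axis=0, prepend=np.zeros((1, n), int))
    rewards = r_food * eaten_step - c_eod * eod.astype(float)

    actions = np.zeros((T, n, 4))
    actions[:, :, 2] = eod
    return EpisodeTrace(
        config=cfg.to_dict(), seed=spec.seed, positions=positions,
        headings=headings, speeds=speeds, actions=actions, rewards=rewards,
        eod=eod.astype(np.uint8), food_eaten=food_eaten,
        dominance=substream(spec.seed, "synthetic-dominance").uniform(0, 1, n),
        patch_centers=np.zeros((0, 2)), items_per_patch=np.zeros((T, 0), int),
        observations=None, obs_layout=block_layout(cfg))
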