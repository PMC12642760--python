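"""Multi-agent PPO on the shared recurrent policy.

Rollouts are collected from parallel arenas; every agent contributes its
(observation, action, reward) stream to one shared parameter update —
parameter sharing across agents, one private hidden state each.  Advantages
use generalized advantage estimation (GAE); updates use the clipped
surrogate with advantage normalization, entropy bonus, value loss and
global-norm gradient clipping.  Recurrent segments are replayed exactly from
hidden-state snapshots taken at rollout starts (burn-in 0).

Rewards contain exactly three terms — food intake, per-EOD energetic cost,
and bite penalties.  Nothing rewards proximity, coordination or
communication; any social structure in trained behavior is emergent.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

from . import autodiff as ad
from .config import ArenaConfig
from .policy import (PolicyConfig, PolicyState, forward_np, forward_tape,
                     init_policy, log_prob_np, log_prob_tape, entropy_tape,
                     ActionDistribution, sample_action)
from .rng import child_seed, substream
from .sensors import assemble_observation
from .trace import EpisodeTrace, TraceRecorder
from .world import World

__all__ = ["TrainConfig", "RolloutBatch", "reward_fn", "REWARD_TERMS", "gae",
           "ppo_update", "train", "collect_rollout", "rollout_episode",
           "evaluate_policy", "random_actions"]

#: The complete list of reward terms; no social/coordination term exists.
REWARD_TERMS = ("food", "eod_cost", "bite")


def reward_fn(events: dict, config: ArenaConfig) -> np.ndarray:
    """Assemble per-agent rewards from step events.

    ``events`` carries ``items_eaten`` (count per agent), ``eod`` (flag per
    agent) and ``bite_deltas`` (per-agent deltas from resolve_bites).
    """
    return (config.r_food * np.asarray(events["items_eaten"], float)
            - config.c_eod * np.asarray(events["eod"], float)
            + np.asarray(events["bite_deltas"], float))


@dataclass
class TrainConfig:
    gamma: float = 0.99
    gae_lambda: float = 0.95
    clip_eps: float = 0.2
    epochs_per_batch: int = 4
    n_minibatches: int = 1          # minibatches of whole sequences
    learning_rate: float = 3e-4
    entropy_coef: float = 0.01
    value_coef: float = 0.5
    max_grad_norm: float = 0.5
    rollout_T: int = 128
    n_parallel_envs: int = 8
    total_env_steps: int = 200_000
    seed: int = 0
    centralized_critic: bool = False

    def __post_init__(self) -> None:
        if not (0.0 < self.gamma <= 1.0):
            raise ValueError("gamma must be in (0, 1]")
        if not (0.0 <= self.gae_lambda <= 1.0):
            raise ValueError("gae_lambda must be in [0, 1]")
        if self.clip_eps <= 0 or self.learning_rate <= 0:
            raise ValueError("clip_eps and learning_rate must be positive")
        if self.rollout_T < 2:
            raise ValueError("rollout length must be >= 2")


@dataclass
class RolloutBatch:
    obs: np.ndarray          # (T, B, D)   B = n_envs * n_agents sequences
    actions: np.ndarray      # (T, B, 4)
    log_probs: np.ndarray    # (T, B)
    rewards: np.ndarray      # (T, B)
    values: np.ndarray       # (T, B)
    dones: np.ndarray        # (T, B)  1.0 where the episode ended at t
    h0: np.ndarray           # (B, R) hidden snapshot at segment start
    bootstrap_value: np.ndarray  # (B,)
    obs_all: Optional[np.ndarray] = None  # (T, E, N*D) for the centralized critic


def gae(rewards: np.ndarray, values: np.ndarray, dones: np.ndarray,
        gamma: float, lam: float) -> Tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation.

    ``values`` has one more row than ``rewards`` (bootstrap appended).
    delta_t = r_t + gamma V_{t+1} (1-done_t) - V_t;
    A_t = delta_t + gamma lam (1-done_t) A_{t+1}; returns = A + V.
    """
    rewards = np.asarray(rewards, float)
    values = np.asarray(values, float)
    dones = np.asarray(dones, float)
    T = rewards.shape[0]
    if values.shape[0] != T + 1 or dones.shape[0] != T:
        raise ValueError("gae: need values of length T+1 and dones of length T")
    adv = np.zeros_like(rewards)
    last = np.zeros_like(rewards[0] if rewards.ndim > 1 else np.zeros(()))
    for t in range(T - 1, -1, -1):
        nonterm = 1.0 - dones[t]
        delta = rewards[t] + gamma * values[t + 1] * nonterm - values[t]
        last = delta + gamma * lam * nonterm * last
        adv[t] = last
    return adv, adv + values[:-1]


# -- optimizer -----------------------------------------------------------


class _Adam:
    def __init__(self, shapes: Dict[str, tuple], lr: float,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = {k: np.zeros(s) for k, s in shapes.items()}
        self.v = {k: np.zeros(s) for k, s in shapes.items()}
        self.t = 0

    def step(self, params: Dict[str, np.ndarray], grads: Dict[str, np.ndarray]):
        self.t += 1
        b1t, b2t = 1 - self.b1 ** self.t, 1 - self.b2 ** self.t
        for k, g in grads.items():
            self.m[k] = self.b1 * self.m[k] + (1 - self.b1) * g
            self.v[k] = self.b2 * self.v[k] + (1 - self.b2) * g * g
            params[k] = params[k] - self.lr * (self.m[k] / b1t) / (
                np.sqrt(self.v[k] / b2t) + self.eps)


def _clip_global_norm(grads: Dict[str, np.ndarray], max_norm: float) -> float:
    total = np.sqrt(sum(float((g ** 2).sum()) for g in grads.values()))
    if total > max_norm and total > 0:
        scale = max_norm / total
        for k in grads:
            grads[k] = grads[k] * scale
    return total


# -- PPO update ----------------------------------------------------------


class CentralCritic:
    """MAPPO-style centralized value function.

    A two-layer tanh MLP mapping the concatenation of *all* agents'
    observations plus a one-hot agent index to that agent's value.  Purely
    feedforward (no recurrence), trained by MSE on GAE returns with its own
    optimizer; the shared policy's recurrent critic head is bypassed when
    this is enabled.
    """

    def __init__(self, n_agents: int, obs_dim: int, width: int, seed: int,
                 lr: float):
        from .policy import _glorot
        rng = substream(seed, "central-critic-init")
        d_in = n_agents * obs_dim + n_agents
        self.n_agents, self.obs_dim = n_agents, obs_dim
        self.params = {"Wv1": _glorot(rng, d_in, width), "bv1": np.zeros(width),
                       "Wv2": _glorot(rng, width, width), "bv2": np.zeros(width),
                       "Wvo": 0.01 * _glorot(rng, width, 1), "bvo": np.zeros(1)}
        self.opt = _Adam({k: v.shape for k, v in self.params.items()}, lr)

    def _inputs(self, obs_all: np.ndarray) -> np.ndarray:
        """(..., E, N*D) -> (E*N, N*D+N) with a one-hot agent index."""
        flat = obs_all.reshape(-1, self.n_agents * self.obs_dim)
        E = flat.shape[0]
        rep = np.repeat(flat, self.n_agents, axis=0)
        eye = np.tile(np.eye(self.n_agents), (E, 1))
        return np.concatenate([rep, eye], axis=1)

    def values_np(self, obs_all: np.ndarray) -> np.ndarray:
        """(E, N*D) -> (E, N) per-agent values."""
        x = self._inputs(obs_all)
        p = self.params
        h = np.tanh(x @ p["Wv1"] + p["bv1"])
        h = np.tanh(h @ p["Wv2"] + p["bv2"])
        return (h @ p["Wvo"] + p["bvo"]).reshape(-1, self.n_agents)

    def update(self, obs_all: np.ndarray, returns: np.ndarray,
               max_grad_norm: float) -> float:
        """One MSE gradient step; ``obs_all`` (T,E,N*D), ``returns`` (T,E*N)."""
        x = self._inputs(obs_all)
        pt = {k: ad.parameter(v) for k, v in self.params.items()}
        h = ad.tanh(ad.matmul(ad.constant(x), pt["Wv1"]) + pt["bv1"])
        h = ad.tanh(ad.matmul(h, pt["Wv2"]) + pt["bv2"])
        v = (ad.matmul(h, pt["Wvo"]) + pt["bvo"]).reshape(-1)
        loss = ((v - returns.reshape(-1)) ** 2).mean()
        loss.backward()
        grads = {k: t.grad for k, t in pt.items()}
        _clip_global_norm(grads, max_grad_norm)
        self.opt.step(self.params, grads)
        return float(loss.data)


def ppo_loss_tape(params_t: Dict[str, ad.Tensor], pcfg: PolicyConfig,
                  batch: RolloutBatch, seq_idx: np.ndarray, cfg: TrainConfig,
                  advantages: np.ndarray, returns: np.ndarray,
                  use_value_head: bool = True):
    """Build the clipped-surrogate PPO loss on the tape for a minibatch of
    whole sequences; returns (loss tensor, diagnostics dict)."""
    from .policy import _cell_tape, heads_tape
    T = batch.obs.shape[0]
    Bmb = len(seq_idx)
    h = ad.constant(batch.h0[seq_idx])
    h_rows = []
    for t in range(T):
        h = _cell_tape(params_t, pcfg, ad.constant(batch.obs[t, seq_idx]), h)
        h_rows.append(h)
        mask = (1.0 - batch.dones[t, seq_idx])[:, None]
        h = h * mask
    hs = ad.stack(h_rows, axis=0).reshape(T * Bmb, pcfg.rnn_width)
    raw, value = heads_tape(params_t, hs)
    acts = batch.actions[:, seq_idx].reshape(T * Bmb, 4)
    lp_new = log_prob_tape(raw, acts).reshape(T, Bmb)
    v_new = value.reshape(T, Bmb)
    entropy = entropy_tape(raw).reshape(T, Bmb)

    adv = advantages[:, seq_idx]
    ret = returns[:, seq_idx]
    old_lp = batch.log_probs[:, seq_idx]
    ratio = ad.exp(lp_new - old_lp)
    clipped = ad.clip(ratio, 1.0 - cfg.clip_eps, 1.0 + cfg.clip_eps)
    surrogate = ad.minimum(ratio * adv, clipped * adv)
    pg_loss = -surrogate.mean()
    ent_mean = entropy.mean()
    loss = pg_loss - cfg.entropy_coef * ent_mean
    v_loss = 0.0
    if use_value_head:
        v_loss_t = ((v_new - ret) ** 2).mean()
        loss = loss + cfg.value_coef * v_loss_t
        v_loss = float(v_loss_t.data)
    diag = {"ratio": ratio.data, "pg_loss": float(pg_loss.data),
            "v_loss": v_loss, "entropy": float(ent_mean.data)}
    return loss, diag


def ppo_update(policy: PolicyState, batch: RolloutBatch, cfg: TrainConfig,
               optimizer: Optional[_Adam] = None,
               rng: Optional[np.random.Generator] = None,
               normalize_adv: bool = True,
               critic: Optional[CentralCritic] = None) -> dict:
    """One PPO update (epochs x minibatches) on the shared parameters in place."""
    if optimizer is None:
        optimizer = _Adam({k: v.shape for k, v in policy.params.items()},
                          cfg.learning_rate)
    if rng is None:
        rng = substream(cfg.seed, "ppo-minibatch")
    advantages, returns = gae(batch.rewards,
                              np.vstack([batch.values, batch.bootstrap_value[None, :]]),
                              batch.dones, cfg.gamma, cfg.gae_lambda)
    if normalize_adv:
        advantages = (advantages - advantages.mean()) / (advantages.std() + 1e-8)

    B = batch.obs.shape[1]
    stats: dict = {}
    for epoch in range(cfg.epochs_per_batch):
        if critic is not None:
            stats["critic_loss"] = critic.update(batch.obs_all, returns,
                                                 cfg.max_grad_norm)
        order = rng.permutation(B)
        for mb in np.array_split(order, min(cfg.n_minibatches, B)):
            params_t = {k: ad.parameter(v) for k, v in policy.params.items()}
            loss, diag = ppo_loss_tape(params_t, policy.config, batch, mb,
                                       cfg, advantages, returns,
                                       use_value_head=critic is None)
            if not np.isfinite(loss.data):
                raise RuntimeError(
                    f"non-finite PPO loss (pg={diag['pg_loss']}, "
                    f"v={diag['v_loss']}, H={diag['entropy']})")
            loss.backward()
            grads = {k: (t.grad if t.grad is not None else np.zeros_like(t.data))
                     for k, t in params_t.items()}
            grad_norm = _clip_global_norm(grads, cfg.max_grad_norm)
            optimizer.step(policy.params, grads)
            stats.update({"loss": float(loss.data), "grad_norm": grad_norm, **diag})
            stats["ratio"] = None  # large; keep scalars only
    stats["mean_advantage"] = float(advantages.mean())
    return stats


# -- rollout collection --------------------------------------------------


def _observe_all(worlds: List[World], noise_rngs=None) -> np.ndarray:
    """(E, N, D) observations for all envs/agents."""
    obs = []
    for e, w in enumerate(worlds):
        rng = noise_rngs[e] if noise_rngs else None
        obs.append([assemble_observation(w, i, rng) for i in range(w.config.n_agents)])
    return np.asarray(obs, float)


def collect_rollout(policy: PolicyState, worlds: List[World],
                    hidden: np.ndarray, cfg: TrainConfig,
                    action_rng: np.random.Generator,
                    episode_counter: List[int],
                    episode_log: List[dict],
                    critic: Optional[CentralCritic] = None
                    ) -> Tuple[RolloutBatch, np.ndarray]:
    """Advance all parallel worlds ``rollout_T`` steps under the current
    policy; returns the batch and the carried hidden state."""
    E = len(worlds)
    N = worlds[0].config.n_agents
    D = worlds[0].config.obs_dim
    T, R = cfg.rollout_T, policy.config.rnn_width
    pcfg = policy.config

    obs_buf = np.zeros((T, E, N, D))
    act_buf = np.zeros((T, E, N, 4))
    lp_buf = np.zeros((T, E, N))
    rew_buf = np.zeros((T, E, N))
    val_buf = np.zeros((T, E, N))
    done_buf = np.zeros((T, E, N))
    h0 = hidden.reshape(E * N, R).copy()

    for t in range(T):
        obs = _observe_all(worlds)
        obs_buf[t] = obs
        raw, value, h_new = forward_np(policy.params, pcfg,
                                       obs.reshape(E * N, D),
                                       hidden.reshape(E * N, R))
        actions, lp = sample_action(ActionDistribution(raw), action_rng)
        act_buf[t] = actions.reshape(E, N, 4)
        lp_buf[t] = lp.reshape(E, N)
        val_buf[t] = (critic.values_np(obs.reshape(E, N * D))
                      if critic is not None else value.reshape(E, N))
        hidden = h_new.reshape(E, N, R)
        for e, w in enumerate(worlds):
            rewards, done = w.step(act_buf[t, e])
            rew_buf[t, e] = rewards
            if done:
                done_buf[t, e, :] = 1.0
                episode_log.append({
                    "episode": episode_counter[0],
                    "food_per_agent": float(w.food_eaten.mean()),
                    "reward_per_agent": float(w.cumulative_reward.mean()),
                    "eod_rate": float(w.eod.mean())})
                episode_counter[0] += 1
                w.reset(child_seed(cfg.seed, "episode", episode_counter[0]))
                hidden[e] = 0.0

    final_obs = _observe_all(worlds)
    if critic is not None:
        boot_val = critic.values_np(final_obs.reshape(E, N * D)).reshape(E * N)
    else:
        _, boot_val, _ = forward_np(policy.params, pcfg,
                                    final_obs.reshape(E * N, D),
                                    hidden.reshape(E * N, R))
    batch = RolloutBatch(
        obs=obs_buf.reshape(T, E * N, D), actions=act_buf.reshape(T, E * N, 4),
        log_probs=lp_buf.reshape(T, E * N), rewards=rew_buf.reshape(T, E * N),
        values=val_buf.reshape(T, E * N), dones=done_buf.reshape(T, E * N),
        h0=h0, bootstrap_value=boot_val,
        obs_all=obs_buf.reshape(T, E, N * D) if critic is not None else None)
    return batch, hidden


def train(arena: ArenaConfig, policy_cfg: PolicyConfig, cfg: TrainConfig,
          log_path: Optional[str] = None,
          progress: bool = False) -> Tuple[PolicyState, pd.DataFrame]:
    """Full training loop: collect -> GAE -> clipped PPO, fully seeded."""
    if policy_cfg.obs_dim != arena.obs_dim:
        raise ValueError("policy obs_dim does not match the arena's")
    policy = init_policy(policy_cfg, cfg.seed, n_agents=arena.n_agents)
    optimizer = _Adam({k: v.shape for k, v in policy.params.items()},
                      cfg.learning_rate)
    mb_rng = substream(cfg.seed, "ppo-minibatch")
    action_rng = substream(cfg.seed, "actions")
    critic = (CentralCritic(arena.n_agents, arena.obs_dim, policy_cfg.head_width,
                            cfg.seed, cfg.learning_rate)
              if cfg.centralized_critic else None)
    E = cfg.n_parallel_envs
    worlds = [World(arena, seed=child_seed(cfg.seed, "env", e)) for e in range(E)]
    hidden = np.zeros((E, arena.n_agents, policy_cfg.rnn_width))

    steps_per_iter = E * cfg.rollout_T
    n_iters = max(0, cfg.total_env_steps // steps_per_iter)
    episode_counter = [0]
    rows = []
    t_start = time.time()
    for it in range(n_iters):
        episode_log: List[dict] = []
        batch, hidden = collect_rollout(policy, worlds, hidden, cfg,
                                        action_rng, episode_counter, episode_log,
                                        critic=critic)
        stats = ppo_update(policy, batch, cfg, optimizer, mb_rng, critic=critic)
        row = {"iteration": it, "env_steps": (it + 1) * steps_per_iter,
               "mean_reward": float(batch.rewards.mean()),
               "mean_food": (float(np.mean([e["food_per_agent"] for e in episode_log]))
                             if episode_log else np.nan),
               "mean_eod_rate": float(batch.actions[:, :, 2].mean()),
               "loss": stats["loss"], "entropy": stats["entropy"],
               "elapsed_s": round(time.time() - t_start, 2)}
        rows.append(row)
        if progress and (it % 10 == 0 or it == n_iters - 1):
            print(f"iter {it:4d} steps {row['env_steps']:8d} "
                  f"reward {row['mean_reward']:+.4f} eod {row['mean_eod_rate']:.3f}")
    log = pd.DataFrame(rows)
    if log_path is not None:
        log.to_csv(log_path, index=False)
    return policy, log


# -- evaluation / scripted rollouts --------------------------------------


def random_actions(n_agents: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random policy: the evaluation baseline."""
    return np.column_stack([rng.uniform(0, 1, n_agents),
                            rng.uniform(-1, 1, n_agents),
                            (rng.uniform(size=n_agents) < 0.5).astype(float),
                            (rng.uniform(size=n_agents) < 0.5).astype(float)])


def rollout_episode(arena: ArenaConfig, seed: int,
                    policy: Optional[PolicyState] = None,
                    scripted=None, deterministic: bool = False,
                    record_obs: bool = False, max_steps: Optional[int] = None
                    ) -> Tuple[EpisodeTrace, World]:
    """Run one full episode and record its trace.

    ``policy`` uses the trained controller; ``scripted`` is a callable
    ``(world, t, rng) -> (N, 4) action array``; with neither, actions are
    uniform random.
    """
    world = World(arena, seed=seed)
    rng = substream(seed, "rollout-actions")
    rec = TraceRecorder(arena, seed, record_obs=record_obs)
    hidden = np.zeros((arena.n_agents, policy.config.rnn_width)) if policy else None
    steps = max_steps if max_steps is not None else arena.max_steps
    for t in range(steps):
        obs = None
        if policy is not None:
            obs = np.array([assemble_observation(world, i)
                            for i in range(arena.n_agents)])
            raw, _, hidden = forward_np(policy.params, policy.config, obs, hidden)
            actions, _ = sample_action(ActionDistribution(raw), rng,
                                       deterministic=deterministic)
        elif scripted is not None:
            actions = np.asarray(scripted(world, t, rng), float)
        else:
            actions = random_actions(arena.n_agents, rng)
        rewards, done = world.step(actions)
        rec.record(world, actions, rewards,
                   obs if record_obs and obs is not None else None)
        if done:
            break
    return rec.finalize(), world


def evaluate_policy(arena: ArenaConfig, policy: Optional[PolicyState],
                    n_episodes: int, seed: int,
                    deterministic: bool = False) -> pd.DataFrame:
    """Per-episode food/reward summary for a policy (None = random baseline)."""
    rows = []
    for ep in range(n_episodes):
        ep_seed = child_seed(seed, "eval-episode", ep)
        trace, world = rollout_episode(arena, ep_seed, policy=policy,
                                       deterministic=deterministic)
        rows.append({"episode": ep, "seed": ep_seed,
                     "food_per_agent": float(world.food_eaten.mean()),
                     "reward_per_agent": float(world.cumulative_reward.mean()),
                     "eod_rate": float(trace.eod.mean())})
    return pd.DataFrame(rows)
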