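"""Recurrent actor-critic controller.

All agents share one parameter set (a common underlying network); each agent
keeps a private recurrent hidden vector.  Architecture: a recurrent core
(plain tanh recurrence by default, GRU by config) followed by parallel actor
and critic two-layer feedforward heads, tanh nonlinearities throughout.
Continuous actions (thrust, turn) use Beta distributions on their bounded
supports; EOD and bite are Bernoulli.

The forward pass exists twice with identical op order: a fast NumPy path for
rollouts (`forward_np`) and an autodiff-tape path for PPO updates
(`forward_tape`); the tests assert they agree to float precision.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
from scipy import special

from . import autodiff as ad
from .rng import substream

__all__ = ["PolicyConfig", "PolicyState", "ActionDistribution", "init_policy",
           "policy_step", "forward_np", "forward_tape", "sample_action",
           "log_prob_np", "log_prob_tape", "entropy_tape",
           "save_checkpoint", "load_checkpoint"]

_EPS = 1e-6  # clip actions into the open support of the Beta density
_RAW_DIM = 6  # [thrust_a, thrust_b, turn_a, turn_b, eod_logit, bite_logit]


@dataclass
class PolicyConfig:
    obs_dim: int
    rnn_width: int = 512
    head_width: int = 512
    head_depth: int = 2
    cell: str = "tanh"           # "tanh" | "gru"

    def __post_init__(self) -> None:
        if self.rnn_width < 1 or self.head_width < 1 or self.obs_dim < 1:
            raise ValueError("widths and obs_dim must be >= 1")
        if self.head_depth != 2:
            raise ValueError("heads are two-layer MLPs (head_depth=2)")
        if self.cell not in ("tanh", "gru"):
            raise ValueError("cell must be 'tanh' or 'gru'")


@dataclass
class PolicyState:
    config: PolicyConfig
    params: Dict[str, np.ndarray]
    hidden: np.ndarray           # (n_agents, rnn_width)

    def zero_hidden(self, n_agents: int) -> np.ndarray:
        return np.zeros((n_agents, self.config.rnn_width))


class ActionDistribution:
    """Joint distribution over (thrust, turn, eod, bite) from raw head output."""

    def __init__(self, raw: np.ndarray):
        self.raw = np.atleast_2d(raw)

    @property
    def thrust_ab(self) -> Tuple[np.ndarray, np.ndarray]:
        return (_softplus(self.raw[:, 0]) + 1.0, _softplus(self.raw[:, 1]) + 1.0)

    @property
    def turn_ab(self) -> Tuple[np.ndarray, np.ndarray]:
        return (_softplus(self.raw[:, 2]) + 1.0, _softplus(self.raw[:, 3]) + 1.0)

    @property
    def eod_p(self) -> np.ndarray:
        return special.expit(self.raw[:, 4])

    @property
    def bite_p(self) -> np.ndarray:
        return special.expit(self.raw[:, 5])


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


# -- initialization ------------------------------------------------------


def _orthogonal(rng: np.random.Generator, n: int) -> np.ndarray:
    q, r = np.linalg.qr(rng.normal(size=(n, n)))
    return q * np.sign(np.diag(r))


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int,
            gain: float = 1.0) -> np.ndarray:
    lim = gain * np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-lim, lim, size=(fan_in, fan_out))


def init_policy(config: PolicyConfig, seed: int, n_agents: int = 1) -> PolicyState:
    """Seeded initialization: orthogonal recurrent matrix, Glorot-uniform
    feedforward weights, small output layers, zero biases and hidden state."""
    rng = substream(seed, "policy-init")
    D, R, H = config.obs_dim, config.rnn_width, config.head_width
    p: Dict[str, np.ndarray] = {}
    n_gates = 3 if config.cell == "gru" else 1
    p["Wxh"] = _glorot(rng, D, n_gates * R)
    p["Whh"] = np.concatenate([_orthogonal(rng, R) for _ in range(n_gates)], axis=1)
    p["bh"] = np.zeros(n_gates * R)
    for head in ("a", "c"):
        out_dim = _RAW_DIM if head == "a" else 1
        p[f"W{head}1"] = _glorot(rng, R, H)
        p[f"b{head}1"] = np.zeros(H)
        p[f"W{head}2"] = _glorot(rng, H, H)
        p[f"b{head}2"] = np.zeros(H)
        p[f"W{head}o"] = 0.01 * _glorot(rng, H, out_dim)
        p[f"b{head}o"] = np.zeros(out_dim)
    return PolicyState(config, p, np.zeros((n_agents, R)))


# -- forward passes ------------------------------------------------------


def _cell_np(p, cfg: PolicyConfig, obs: np.ndarray, hidden: np.ndarray) -> np.ndarray:
    if cfg.cell == "tanh":
        return np.tanh(obs @ p["Wxh"] + hidden @ p["Whh"] + p["bh"])
    R = cfg.rnn_width
    pre_x, pre_h = obs @ p["Wxh"], hidden @ p["Whh"]
    z = special.expit(pre_x[:, :R] + pre_h[:, :R] + p["bh"][:R])
    r = special.expit(pre_x[:, R:2 * R] + pre_h[:, R:2 * R] + p["bh"][R:2 * R])
    n = np.tanh(pre_x[:, 2 * R:] + r * pre_h[:, 2 * R:] + p["bh"][2 * R:])
    return (1.0 - z) * n + z * hidden


def forward_np(params: Dict[str, np.ndarray], cfg: PolicyConfig,
               obs: np.ndarray, hidden: np.ndarray):
    """Rollout forward pass: (raw actor output (B,6), value (B,), new hidden)."""
    obs = np.atleast_2d(obs)
    hidden = np.atleast_2d(hidden)
    h = _cell_np(params, cfg, obs, hidden)
    a = np.tanh(h @ params["Wa1"] + params["ba1"])
    a = np.tanh(a @ params["Wa2"] + params["ba2"])
    raw = a @ params["Wao"] + params["bao"]
    c = np.tanh(h @ params["Wc1"] + params["bc1"])
    c = np.tanh(c @ params["Wc2"] + params["bc2"])
    value = (c @ params["Wco"] + params["bco"])[:, 0]
    return raw, value, h


def _cell_tape(p, cfg: PolicyConfig, obs: ad.Tensor, hidden: ad.Tensor) -> ad.Tensor:
    if cfg.cell == "tanh":
        return ad.tanh(ad.matmul(obs, p["Wxh"]) + ad.matmul(hidden, p["Whh"]) + p["bh"])
    R = cfg.rnn_width
    pre_x, pre_h = ad.matmul(obs, p["Wxh"]), ad.matmul(hidden, p["Whh"])
    z = ad.sigmoid(pre_x[:, :R] + pre_h[:, :R] + p["bh"][:R])
    r = ad.sigmoid(pre_x[:, R:2 * R] + pre_h[:, R:2 * R] + p["bh"][R:2 * R])
    n = ad.tanh(pre_x[:, 2 * R:] + r * pre_h[:, 2 * R:] + p["bh"][2 * R:])
    return (1.0 - z) * n + z * hidden


def heads_tape(params: Dict[str, ad.Tensor], h: ad.Tensor):
    """Actor and critic heads on a (B, R) hidden tensor."""
    a = ad.tanh(ad.matmul(h, params["Wa1"]) + params["ba1"])
    a = ad.tanh(ad.matmul(a, params["Wa2"]) + params["ba2"])
    raw = ad.matmul(a, params["Wao"]) + params["bao"]
    c = ad.tanh(ad.matmul(h, params["Wc1"]) + params["bc1"])
    c = ad.tanh(ad.matmul(c, params["Wc2"]) + params["bc2"])
    value = ad.matmul(c, params["Wco"]) + params["bco"]
    return raw, value


def forward_tape(params: Dict[str, ad.Tensor], cfg: PolicyConfig,
                 obs: ad.Tensor, hidden: ad.Tensor):
    """Autodiff twin of forward_np (same op order)."""
    h = _cell_tape(params, cfg, obs, hidden)
    raw, value = heads_tape(params, h)
    return raw, value, h


def policy_step(state: PolicyState, obs: np.ndarray, agent_idx: int = 0):
    """One controller step for one agent: (ActionDistribution, value, new hidden).

    Pure function of (parameters, hidden, obs); the caller stores the
    returned hidden vector back into the state it manages.
    """
    obs = np.asarray(obs, float)
    if obs.shape[-1] != state.config.obs_dim:
        raise ValueError(f"obs length {obs.shape[-1]} != configured {state.config.obs_dim}")
    raw, value, h = forward_np(state.params, state.config, obs[None, :],
                               state.hidden[agent_idx][None, :])
    return ActionDistribution(raw), float(value[0]), h[0]


# -- densities, sampling, entropy ---------------------------------------


def _beta_logpdf_np(x: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    x = np.clip(x, _EPS, 1.0 - _EPS)
    return ((a - 1.0) * np.log(x) + (b - 1.0) * np.log(1.0 - x)
            - (special.gammaln(a) + special.gammaln(b) - special.gammaln(a + b)))


def log_prob_np(raw: np.ndarray, actions: np.ndarray) -> np.ndarray:
    """Joint log-probability of actions (B,4) under raw head output (B,6).

    turn is an affine map of a Beta variable (turn = 2 t - 1), so its density
    carries a constant log(1/2) Jacobian.
    """
    ta, tb = _softplus(raw[:, 0]) + 1.0, _softplus(raw[:, 1]) + 1.0
    ua, ub = _softplus(raw[:, 2]) + 1.0, _softplus(raw[:, 3]) + 1.0
    lp = _beta_logpdf_np(actions[:, 0], ta, tb)
    lp = lp + _beta_logpdf_np((actions[:, 1] + 1.0) / 2.0, ua, ub) + np.log(0.5)
    for k, col in ((4, 2), (5, 3)):
        logit = raw[:, k]
        lp = lp + actions[:, col] * logit - _softplus(logit)
    return lp


def log_prob_tape(raw: ad.Tensor, actions: np.ndarray) -> ad.Tensor:
    """Tape twin of log_prob_np; ``actions`` are constants."""
    def beta_lp(x, a, b):
        x = np.clip(x, _EPS, 1.0 - _EPS)
        lnB = ad.gammaln(a) + ad.gammaln(b) - ad.gammaln(a + b)
        return (a - 1.0) * np.log(x) + (b - 1.0) * np.log(1.0 - x) - lnB

    ta = ad.softplus(raw[:, 0]) + 1.0
    tb = ad.softplus(raw[:, 1]) + 1.0
    ua = ad.softplus(raw[:, 2]) + 1.0
    ub = ad.softplus(raw[:, 3]) + 1.0
    lp = beta_lp(actions[:, 0], ta, tb)
    lp = lp + beta_lp((actions[:, 1] + 1.0) / 2.0, ua, ub) + np.log(0.5)
    for k, col in ((4, 2), (5, 3)):
        logit = raw[:, k]
        lp = lp + actions[:, col] * logit - ad.softplus(logit)
    return lp


def entropy_tape(raw: ad.Tensor) -> ad.Tensor:
    """Joint entropy (sum over heads) for the PPO entropy bonus."""
    def beta_entropy(a, b):
        lnB = ad.gammaln(a) + ad.gammaln(b) - ad.gammaln(a + b)
        return (lnB - (a - 1.0) * ad.digamma(a) - (b - 1.0) * ad.digamma(b)
                + (a + b - 2.0) * ad.digamma(a + b))

    ent = beta_entropy(ad.softplus(raw[:, 0]) + 1.0, ad.softplus(raw[:, 1]) + 1.0)
    ent = ent + beta_entropy(ad.softplus(raw[:, 2]) + 1.0, ad.softplus(raw[:, 3]) + 1.0)
    for k in (4, 5):
        logit = raw[:, k]
        ent = ent + ad.softplus(logit) - ad.sigmoid(logit) * logit
    return ent


def sample_action(dist: ActionDistribution, rng: np.random.Generator,
                  deterministic: bool = False):
    """Sample (actions (B,4), joint log-prob (B,)); deterministic mode takes
    the Beta means and thresholds the Bernoulli heads at 0.5."""
    ta, tb = dist.thrust_ab
    ua, ub = dist.turn_ab
    if deterministic:
        thrust = ta / (ta + tb)
        turn = 2.0 * ua / (ua + ub) - 1.0
        eod = (dist.eod_p > 0.5).astype(float)
        bite = (dist.bite_p > 0.5).astype(float)
    else:
        thrust = rng.beta(ta, tb)
        turn = 2.0 * rng.beta(ua, ub) - 1.0
        eod = (rng.uniform(size=ta.shape) < dist.eod_p).astype(float)
        bite = (rng.uniform(size=ta.shape) < dist.bite_p).astype(float)
    actions = np.column_stack([thrust, turn, eod, bite])
    return actions, log_prob_np(dist.raw, actions)


# -- checkpoints ---------------------------------------------------------


def save_checkpoint(path: str, state: PolicyState) -> None:
    meta = json.dumps({"obs_dim": state.config.obs_dim,
                       "rnn_width": state.config.rnn_width,
                       "head_width": state.config.head_width,
                       "head_depth": state.config.head_depth,
                       "cell": state.config.cell})
    np.savez(path, __meta__=np.frombuffer(meta.encode(), dtype=np.uint8),
             **state.params)


def load_checkpoint(path: str, expected: Optional[PolicyConfig] = None) -> PolicyState:
    with np.load(path) as z:
        meta = json.loads(bytes(z["__meta__"]).decode())
        params = {k: z[k] for k in z.files if k != "__meta__"}
    cfg = PolicyConfig(**meta)
    if expected is not None and cfg != expected:
        raise ValueError(f"checkpoint config {meta} does not match expected {expected}")
    return PolicyState(cfg, params, np.zeros((1, cfg.rnn_width)))
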