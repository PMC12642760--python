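"""PPO machinery: reward assembly, GAE oracles, clipping, determinism."""

import numpy as np
import pytest

from efish import autodiff as ad
from efish.config import ArenaConfig
from efish.policy import (ActionDistribution, PolicyConfig, forward_np,
                          init_policy, sample_action)
from efish.training import (REWARD_TERMS, CentralCritic, RolloutBatch,
                            TrainConfig, collect_rollout, gae, ppo_loss_tape,
                            ppo_update, reward_fn, train)
from efish.world import World
from efish.rng import substream


class TestRewardFn:
    def test_single_terms(self):
        cfg = ArenaConfig()
        ev = {"items_eaten": [1, 0], "eod": [0, 0], "bite_deltas": [0.0, 0.0]}
        np.testing.assert_allclose(reward_fn(ev, cfg), [cfg.r_food, 0.0])
        ev = {"items_eaten": [0, 0], "eod": [1, 0], "bite_deltas": [0.0, 0.0]}
        np.testing.assert_allclose(reward_fn(ev, cfg), [-cfg.c_eod, 0.0])

    def test_composite_is_sum_of_terms(self, rng):
        cfg = ArenaConfig()
        for _ in range(20):
            ev = {"items_eaten": rng.integers(0, 3, 4),
                  "eod": rng.integers(0, 2, 4),
                  "bite_deltas": rng.normal(size=4)}
            total = reward_fn(ev, cfg)
            manual = (cfg.r_food * ev["items_eaten"]
                      - cfg.c_eod * ev["eod"] + ev["bite_deltas"])
            np.testing.assert_allclose(total, manual)

    def test_no_social_reward_terms(self):
        # the full term list: foraging, discharge cost, bite penalties —
        # nothing rewards proximity, coordination, or communication
        assert set(REWARD_TERMS) == {"food", "eod_cost", "bite"}
        cfg = ArenaConfig()
        ev = {"items_eaten": [0, 0], "eod": [0, 0], "bite_deltas": [0.0, 0.0]}
        np.testing.assert_allclose(reward_fn(ev, cfg), 0.0)


class TestGAE:
    def test_lambda_zero_is_td_error(self, rng):
        T = 20
        r = rng.normal(size=T)
        v = rng.normal(size=T + 1)
        d = np.zeros(T)
        adv, ret = gae(r, v, d, gamma=0.9, lam=0.0)
        delta = r + 0.9 * v[1:] - v[:-1]
        np.testing.assert_allclose(adv, delta, rtol=1e-12)
        np.testing.assert_allclose(ret, adv + v[:-1])

    def test_monte_carlo_limit(self, rng):
        T = 30
        r = rng.normal(size=T)
        v = np.zeros(T + 1)
        adv, _ = gae(r, v, np.zeros(T), gamma=1.0, lam=1.0)
        suffix = np.cumsum(r[::-1])[::-1]
        np.testing.assert_allclose(adv, suffix, rtol=1e-12)

    def test_brute_force_double_sum_oracle(self, rng):
        # A_t = sum_k (gamma*lam)^k delta_{t+k}, truncated at episode ends
        for _ in range(100):
            T = 50
            gamma = rng.uniform(0.8, 1.0)
            lam = rng.uniform(0.0, 1.0)
            r = rng.normal(size=T)
            v = rng.normal(size=T + 1)
            d = (rng.uniform(size=T) < 0.1).astype(float)
            adv, _ = gae(r, v, d, gamma, lam)
            delta = r + gamma * v[1:] * (1 - d) - v[:-1]
            want = np.zeros(T)
            for t in range(T):
                acc, w = 0.0, 1.0
                for k in range(t, T):
                    acc += w * delta[k]
                    if d[k]:
                        break
                    w *= gamma * lam
                want[t] = acc
            np.testing.assert_allclose(adv, want, atol=1e-9)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gae(np.zeros(5), np.zeros(5), np.zeros(5), 0.99, 0.95)


def _make_batch(pcfg, params, T=8, B=3, seed=0):
    rng = np.random.default_rng(seed)
    obs = rng.normal(size=(T, B, pcfg.obs_dim))
    h0 = rng.uniform(-0.3, 0.3, size=(B, pcfg.rnn_width))
    h = h0.copy()
    acts = np.zeros((T, B, 4)); lps = np.zeros((T, B)); vals = np.zeros((T, B))
    for t in range(T):
        raw, v, h = forward_np(params, pcfg, obs[t], h)
        a, lp = sample_action(ActionDistribution(raw), rng)
        acts[t], lps[t], vals[t] = a, lp, v
    return RolloutBatch(obs=obs, actions=acts, log_probs=lps,
                        rewards=rng.normal(size=(T, B)), values=vals,
                        dones=np.zeros((T, B)), h0=h0,
                        bootstrap_value=np.zeros(B))


class TestPPO:
    def setup_method(self):
        self.pcfg = PolicyConfig(obs_dim=10, rnn_width=16, head_width=16)
        self.policy = init_policy(self.pcfg, seed=1)
        self.tcfg = TrainConfig(rollout_T=8)

    def test_first_epoch_ratios_are_one(self):
        batch = _make_batch(self.pcfg, self.policy.params)
        adv, ret = gae(batch.rewards,
                       np.vstack([batch.values, batch.bootstrap_value[None]]),
                       batch.dones, self.tcfg.gamma, self.tcfg.gae_lambda)
        pt = {k: ad.parameter(v) for k, v in self.policy.params.items()}
        _, diag = ppo_loss_tape(pt, self.pcfg, batch, np.arange(3),
                                self.tcfg, adv, ret)
        np.testing.assert_allclose(diag["ratio"], 1.0, atol=1e-6)

    def test_clipped_samples_zero_policy_gradient(self):
        # surrogate gradient w.r.t. new log-prob vanishes exactly where the
        # ratio is clipped on the disadvantageous side
        eps = 0.2
        old_lp = np.zeros(8)
        adv = np.array([1.0, 1.0, -1.0, -1.0, 1.0, -1.0, 1.0, -1.0])
        # choose new log-probs that place ratios in and out of the clip band
        new_lp_vals = np.log(np.array([1.5, 1.0, 0.5, 1.0, 0.9, 1.1, 1.25, 0.75]))
        lp = ad.parameter(new_lp_vals)
        ratio = ad.exp(lp - old_lp)
        clipped = ad.clip(ratio, 1 - eps, 1 + eps)
        (-ad.minimum(ratio * adv, clipped * adv).mean()).backward()
        ratios = np.exp(new_lp_vals)
        should_be_zero = ((ratios > 1 + eps) & (adv > 0)) | \
                         ((ratios < 1 - eps) & (adv < 0))
        np.testing.assert_array_equal(lp.grad == 0.0, should_be_zero)

    def test_zero_advantage_freezes_policy_gradient_term(self):
        batch = _make_batch(self.pcfg, self.policy.params)
        adv = np.zeros_like(batch.rewards)
        ret = batch.values
        pt = {k: ad.parameter(v) for k, v in self.policy.params.items()}
        loss, diag = ppo_loss_tape(pt, self.pcfg, batch, np.arange(3),
                                   self.tcfg, adv, ret)
        assert diag["pg_loss"] == pytest.approx(0.0, abs=1e-12)

    def test_update_moves_parameters_and_is_finite(self):
        batch = _make_batch(self.pcfg, self.policy.params)
        before = {k: v.copy() for k, v in self.policy.params.items()}
        stats = ppo_update(self.policy, batch, self.tcfg)
        assert np.isfinite(stats["loss"])
        assert any(np.any(self.policy.params[k] != before[k]) for k in before)

    def test_nonfinite_loss_aborts(self):
        batch = _make_batch(self.pcfg, self.policy.params)
        batch.rewards[0, 0] = np.inf
        with pytest.raises(RuntimeError):
            ppo_update(self.policy, batch, self.tcfg)

    def test_update_gradient_matches_finite_difference(self):
        # single-minibatch update direction equals the finite-difference
        # gradient of the same loss on a 16-unit policy
        batch = _make_batch(self.pcfg, self.policy.params)
        adv, ret = gae(batch.rewards,
                       np.vstack([batch.values, batch.bootstrap_value[None]]),
                       batch.dones, self.tcfg.gamma, self.tcfg.gae_lambda)
        adv_n = (adv - adv.mean()) / (adv.std() + 1e-8)
        pt = {k: ad.parameter(v) for k, v in self.policy.params.items()}
        loss, _ = ppo_loss_tape(pt, self.pcfg, batch, np.arange(3),
                                self.tcfg, adv_n, ret)
        loss.backward()

        def loss_at(params):
            pt2 = {k: ad.parameter(v) for k, v in params.items()}
            l, _ = ppo_loss_tape(pt2, self.pcfg, batch, np.arange(3),
                                 self.tcfg, adv_n, ret)
            return float(l.data)

        rng = np.random.default_rng(3)
        eps = 1e-6
        for key in ("Whh", "Wxh", "Wao", "Wco", "ba1"):
            g = pt[key].grad
            flat = np.argsort(np.abs(g), axis=None)[-3:]
            for fi in flat:
                idx = np.unravel_index(fi, g.shape)
                p2 = {k: v.copy() for k, v in self.policy.params.items()}
                p2[key][idx] += eps
                up = loss_at(p2)
                p2[key][idx] -= 2 * eps
                dn = loss_at(p2)
                fd = (up - dn) / (2 * eps)
                assert g[idx] == pytest.approx(fd, rel=1e-4, abs=1e-8)


class TestTrainLoop:
    def _arena(self):
        return ArenaConfig(width_cm=50, height_cm=50, n_agents=1, n_patches=2,
                           patch_radius_cm=6, patch_capacity=2,
                           competition=False, max_steps=64)

    def test_zero_steps_returns_initial_policy(self):
        arena = self._arena()
        pcfg = PolicyConfig(obs_dim=arena.obs_dim, rnn_width=8, head_width=8)
        tcfg = TrainConfig(seed=0, total_env_steps=0)
        policy, log = train(arena, pcfg, tcfg)
        ref = init_policy(pcfg, 0, n_agents=1)
        for k in policy.params:
            np.testing.assert_array_equal(policy.params[k], ref.params[k])
        assert len(log) == 0

    def test_training_log_deterministic(self):
        arena = self._arena()
        pcfg = PolicyConfig(obs_dim=arena.obs_dim, rnn_width=8, head_width=8)
        tcfg = TrainConfig(seed=5, total_env_steps=2048, rollout_T=64,
                           n_parallel_envs=2)
        p1, log1 = train(arena, pcfg, tcfg)
        p2, log2 = train(arena, pcfg, tcfg)
        drop = [c for c in log1.columns if c != "elapsed_s"]
        assert log1[drop].equals(log2[drop])
        for k in p1.params:
            np.testing.assert_array_equal(p1.params[k], p2.params[k])

    def test_centralized_critic_variant_runs(self):
        arena = self._arena().replace(n_agents=2)
        pcfg = PolicyConfig(obs_dim=arena.obs_dim, rnn_width=8, head_width=8)
        tcfg = TrainConfig(seed=0, total_env_steps=512, rollout_T=32,
                           n_parallel_envs=2, centralized_critic=True)
        policy, log = train(arena, pcfg, tcfg)
        # 512 env steps / (2 envs * 32-step rollouts) = 8 iterations
        assert len(log) == 8
        assert np.isfinite(log["loss"]).all()

    def test_central_critic_value_shapes(self):
        critic = CentralCritic(n_agents=3, obs_dim=5, width=8, seed=0, lr=1e-3)
        obs_all = np.random.default_rng(0).normal(size=(4, 15))
        v = critic.values_np(obs_all)
        assert v.shape == (4, 3)
        loss = critic.update(obs_all[None], np.zeros((1, 12)), 0.5)
        assert np.isfinite(loss)
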