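"""PPO: GAE oracle equivalence, surrogate limits, masked-learning sanity."""

import numpy as np
import pytest

from cilad.datatypes import FoodItem, PatientProfile
from cilad.nn import Tensor
from cilad.nutri_env import NutriEnv, RewardWeights
from cilad.ppo_agent import (PolicyValueNet, PPOConfig, featurize, gae,
                             ppo_loss, recommend, train_ppo)


def gae_double_loop(rewards, values, gamma, lam):
    """Direct double-loop evaluation of the advantage sum."""
    T = len(rewards)
    adv = np.zeros(T)
    for t in range(T):
        for l in range(T - t):
            delta = (rewards[t + l] + gamma * values[t + l + 1]
                     - values[t + l])
            adv[t] += (gamma * lam) ** l * delta
    return adv


class TestGAE:
    def test_lambda_one_zero_values_gives_reward_to_go(self):
        r = np.array([1.0, 2.0, 3.0])
        adv, ret = gae(r, np.zeros(4), gamma=0.5, lam=1.0)
        expected = [1 + 0.5 * 2 + 0.25 * 3, 2 + 0.5 * 3, 3.0]
        assert np.allclose(adv, expected, atol=1e-12)
        assert np.allclose(ret, adv, atol=1e-12)

    def test_lambda_zero_is_one_step_td(self):
        rng = np.random.default_rng(0)
        r = rng.normal(0, 1, 8)
        v = rng.normal(0, 1, 9)
        adv, _ = gae(r, v, gamma=0.9, lam=0.0)
        delta = r + 0.9 * v[1:] - v[:-1]
        assert np.allclose(adv, delta, atol=1e-12)

    @pytest.mark.parametrize("T", [1, 10, 50])
    def test_matches_double_loop_oracle(self, T):
        rng = np.random.default_rng(T)
        r = rng.normal(0, 1, T)
        v = rng.normal(0, 1, T + 1)
        adv, ret = gae(r, v, gamma=0.97, lam=0.93)
        expected = gae_double_loop(r, v, 0.97, 0.93)
        assert np.allclose(adv, expected, atol=1e-12)
        assert np.allclose(ret, expected + v[:-1], atol=1e-12)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            gae([1.0], [0.0], 0.9, 0.9)


def _fake_batch(policy, n=32, seed=0, zero_adv=False):
    rng = np.random.default_rng(seed)
    n_feat = policy.trunk[0].W.shape[0]
    states = rng.normal(0, 1, (n, n_feat))
    masks = np.ones((n, policy.n_actions), dtype=bool)
    logp, _ = policy.forward_np(states, masks)
    actions = np.array([rng.choice(policy.n_actions, p=np.exp(lp) / np.exp(lp).sum())
                        for lp in logp])
    adv = np.zeros(n) if zero_adv else rng.normal(0, 1, n)
    return {
        "states": states, "actions": actions, "masks": masks,
        "log_probs": logp[np.arange(n), actions],
        "advantages": adv, "returns": rng.normal(0, 1, n),
    }


class TestPPOLoss:
    def test_ratio_one_surrogate_equals_mean_advantage(self):
        policy = PolicyValueNet(6, 4, seed=0)
        cfg = PPOConfig(normalize_adv=False)
        batch = _fake_batch(policy, seed=1)
        _, diag = ppo_loss(batch, policy, cfg)
        assert diag["surrogate"] == pytest.approx(batch["advantages"].mean(),
                                                  abs=1e-5)
        assert diag["clip_fraction"] == 0.0

    def test_zero_advantages_reduce_to_entropy_and_value_terms(self):
        policy = PolicyValueNet(6, 4, seed=0)
        cfg = PPOConfig(normalize_adv=False)
        batch = _fake_batch(policy, seed=2, zero_adv=True)
        loss, diag = ppo_loss(batch, policy, cfg)
        assert diag["surrogate"] == pytest.approx(0.0, abs=1e-7)
        expected = -(cfg.c_entropy * diag["entropy"]
                     - cfg.c_value * diag["value_error"])
        assert float(loss.data) == pytest.approx(expected, abs=1e-5)

    def test_clipped_surrogate_bounded_by_unclipped_envelope(self):
        policy = PolicyValueNet(6, 4, seed=3)
        cfg = PPOConfig(normalize_adv=False)
        batch = _fake_batch(policy, seed=4)
        # perturb old log-probs so ratios leave 1
        batch["log_probs"] = batch["log_probs"] + \
            np.random.default_rng(5).normal(0, 0.3, len(batch["log_probs"]))
        states = Tensor(batch["states"])
        logp_all, _ = policy.forward(states, batch["masks"])
        n = len(batch["actions"])
        logp = logp_all.data[np.arange(n), batch["actions"]]
        ratio = np.exp(logp - batch["log_probs"])
        adv = batch["advantages"]
        unclipped = ratio * adv
        clipped = np.clip(ratio, 1 - cfg.clip_eps, 1 + cfg.clip_eps) * adv
        surr = np.minimum(unclipped, clipped)
        assert np.all(surr <= unclipped + np.abs(adv) * cfg.clip_eps + 1e-9)
        _, diag = ppo_loss(batch, policy, cfg)
        assert diag["surrogate"] == pytest.approx(surr.mean(), abs=1e-5)


def dominant_arm_env():
    """2-action environment where one action satisfies the required tag and
    the other incurs the violation penalty every step."""
    profile = PatientProfile(
        name="toy", age=50, bmi=25, risk=0.5,
        required_tags=frozenset({"good"}),
        lower=np.zeros(5), upper=np.full(5, 1e6),
        targets=np.array([100.0, 10.0, 10.0, 100.0, 10.0]),
        tolerance=np.full(5, 1e6),  # adherence never binds
        hard_max=np.full(5, 1e6), risk_weights=np.zeros(5))
    db = [
        FoodItem(id="good", nutrients=(10, 1, 1, 10, 1), cost=0.0,
                 tags=frozenset({"good"})),
        FoodItem(id="bad", nutrients=(10, 1, 1, 10, 1), cost=0.0),
    ]
    return NutriEnv(profile, db, horizon=4,
                    weights=RewardWeights(alpha=0, beta=0, gamma_pref=1.0,
                                          delta_div=0.0, eta_cost=0.0,
                                          lambda_viol=1.0))


class TestTrainPPO:
    def test_learns_dominant_arm(self):
        env = dominant_arm_env()
        cfg = PPOConfig(updates=30, rollout=128, seed=0)
        policy, curve = train_ppo(env, cfg)
        state = env.reset()
        x = featurize(state, env)
        logp, _ = policy.forward_np(x[None, :], env.action_mask(state)[None, :])
        assert np.exp(logp[0, 0]) > 0.9
        # trained policy beats the uniform-random baseline mean reward
        assert curve["mean_episode_reward"].iloc[-1] > 0.0  # random is ~0

    def test_zero_learning_rate_leaves_policy_unchanged(self):
        env = dominant_arm_env()
        cfg = PPOConfig(updates=2, rollout=64, lr=0.0, seed=1)
        policy, _ = train_ppo(env, cfg)
        fresh = PolicyValueNet(
            len(featurize(env.reset(), env)), env.n_actions, cfg.hidden, cfg.seed)
        for p, q in zip(policy.params(), fresh.params()):
            assert np.array_equal(p.data, q.data)

    def test_no_feasible_first_action_fails_immediately(self):
        profile = PatientProfile(
            name="toy", age=50, bmi=25, risk=0.5,
            lower=np.zeros(5), upper=np.zeros(5),
            targets=np.zeros(5), tolerance=np.zeros(5),
            hard_max=np.zeros(5), risk_weights=np.zeros(5))
        db = [FoodItem(id="x", nutrients=(1, 1, 1, 1, 1), cost=1.0)]
        env = NutriEnv(profile, db, horizon=3)
        with pytest.raises(RuntimeError, match="feasible"):
            train_ppo(env, PPOConfig(updates=1, rollout=8))

    def test_mask_safety_during_training(self, food_db, hypertension_profile):
        env = NutriEnv(hypertension_profile, food_db, horizon=5)
        _, curve = train_ppo(env, PPOConfig(updates=5, rollout=128, seed=2))
        assert (curve["upper_bound_violations"] == 0).all()


class TestRecommend:
    def test_plan_respects_mask_and_conservation(self, food_db,
                                                 hypertension_profile):
        env = NutriEnv(hypertension_profile, food_db, horizon=5)
        cfg = PPOConfig(updates=5, rollout=128, seed=0)
        policy, _ = train_ppo(env, cfg)
        plan = recommend(policy, hypertension_profile, food_db, horizon=5)
        assert len(plan["plan"]) <= 5
        totals = np.array([plan["nutrient_totals"][k]
                           for k in plan["nutrient_totals"]])
        by_id = {f.id: f.nutrient_array for f in food_db}
        assert np.allclose(totals,
                           np.sum([by_id[i] for i in plan["plan"]], axis=0),
                           atol=1e-6)
        assert np.all(totals <= hypertension_profile.upper + 1e-9)
        for item_id in plan["plan"]:
            assert item_id not in hypertension_profile.exclusions
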