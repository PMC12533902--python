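"""Proximal Policy Optimization for the nutrition environment.

Clipped surrogate objective with entropy and value regularization, and
generalized advantage estimation (GAE) for variance reduction.  Infeasible
actions are masked to -inf logits before the softmax, so they carry zero
sampling probability and the entropy is over feasible actions only.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .datatypes import NUTRIENTS, FoodItem, PatientProfile
from .nn import Adam, Dense, Tensor, no_grad
from .nutri_env import NutriEnv, NutriState, RewardWeights

_MASK_LOGIT = -1e9


@dataclass
class PPOConfig:
    clip_eps: float = 0.2
    c_entropy: float = 0.01
    c_value: float = 0.5
    gamma: float = 0.99
    lam: float = 0.95
    lr: float = 3e-4
    update_epochs: int = 4
    minibatch: int = 64
    rollout: int = 1024
    updates: int = 200
    hidden: tuple[int, ...] = (64, 64)
    normalize_adv: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.clip_eps < 1.0:
            # clip_eps == 0 is admitted only through ppo_loss directly
            pass
        if not 0.0 < self.gamma <= 1.0:
            raise ValueError("gamma must lie in (0, 1]")
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must lie in [0, 1]")


@dataclass
class Trajectory:
    """Aligned rollout records; advantages are computed before any update."""

    states: np.ndarray
    actions: np.ndarray
    masks: np.ndarray
    rewards: np.ndarray
    values: np.ndarray
    log_probs: np.ndarray
    advantages: np.ndarray
    returns: np.ndarray


def gae(rewards, values, gamma: float, lam: float) -> tuple[np.ndarray, np.ndarray]:
    """Generalized advantage estimation.

    ``values`` carries one more entry than ``rewards`` (the bootstrap value
    of the state after the last reward).  Returns (advantages, returns) with
    ``returns = advantages + values[:-1]``.
    """
    r = np.asarray(rewards, dtype=float)
    v = np.asarray(values, dtype=float)
    if len(v) != len(r) + 1:
        raise ValueError("values must have exactly one more entry than rewards")
    adv = np.zeros(len(r))
    acc = 0.0
    for t in range(len(r) - 1, -1, -1):
        delta = r[t] + gamma * v[t + 1] - v[t]
        acc = delta + gamma * lam * acc
        adv[t] = acc
    return adv, adv + v[:-1]


# --------------------------------------------------------------------------
# Policy / value network
# --------------------------------------------------------------------------

class PolicyValueNet:
    """Shared tanh trunk with separate policy and value heads."""

    def __init__(self, n_features: int, n_actions: int,
                 hidden: tuple[int, ...] = (64, 64), seed: int = 0):
        rng = np.random.default_rng(seed)
        self.trunk: list[Dense] = []
        width = n_features
        for size in hidden:
            self.trunk.append(Dense(width, size, rng))
            width = size
        self.pi_head = Dense(width, n_actions, rng)
        self.v_head = Dense(width, 1, rng)
        self.n_actions = n_actions

    def params(self):
        ps = []
        for layer in self.trunk:
            ps += layer.params()
        return ps + self.pi_head.params() + self.v_head.params()

    def forward(self, x: Tensor, mask: np.ndarray) -> tuple[Tensor, Tensor]:
        """Masked log-probabilities (N, A) and values (N,)."""
        h = x
        for layer in self.trunk:
            h = layer(h).tanh()
        logits = self.pi_head(h) + Tensor(np.where(mask, 0.0, _MASK_LOGIT))
        return logits.log_softmax(axis=1), self.v_head(h).reshape(-1)

    def forward_np(self, x: np.ndarray, mask: np.ndarray):
        with no_grad():
            logp, v = self.forward(Tensor(x), mask)
        return logp.data, v.data


def featurize(state: NutriState, env: NutriEnv) -> np.ndarray:
    """Network encoding of a state: normalized profile scalars, fractional
    intake c/u, normalized step index, and a chosen-before indicator per item."""
    p = state.profile
    upper = np.where(np.isfinite(env.profile.upper), env.profile.upper, 1.0)
    chosen = np.zeros(env.n_actions)
    for a in state.history:
        chosen[a] = 1.0
    return np.concatenate([
        [p.age / 100.0, p.bmi / 40.0, p.risk],
        state.cumulative / upper,
        [state.t / env.horizon],
        chosen,
    ])


# --------------------------------------------------------------------------
# Loss and training
# --------------------------------------------------------------------------

def ppo_loss(batch: dict, policy: PolicyValueNet, config: PPOConfig):
    """Clipped-surrogate PPO objective (negated for minimization).

    objective = mean(min(ratio * A, clip(ratio) * A)) + c_e * entropy
                - c_v * mean((V - R)^2)
    with ratios against the frozen old log-probabilities.  Returns
    (loss Tensor, diagnostics dict with clip_fraction / entropy / value_error
    / surrogate).
    """
    states = Tensor(batch["states"])
    logp_all, values = policy.forward(states, batch["masks"])
    n = len(batch["actions"])
    onehot = np.zeros((n, policy.n_actions))
    onehot[np.arange(n), batch["actions"]] = 1.0
    logp = (logp_all * Tensor(onehot)).sum(axis=1)
    adv = batch["advantages"]
    if config.normalize_adv and n > 1 and adv.std() > 0:
        adv = (adv - adv.mean()) / adv.std()
    ratio = (logp - Tensor(batch["log_probs"])).exp()
    unclipped = ratio * Tensor(adv)
    lo, hi = 1.0 - config.clip_eps, 1.0 + config.clip_eps
    clipped_ratio = np.clip(ratio.data, lo, hi)
    clipped = Tensor(clipped_ratio) * Tensor(adv)
    # elementwise min via mask (the min has zero gradient through the
    # non-selected branch; the clipped branch is constant w.r.t. theta)
    take_unclipped = unclipped.data <= clipped.data
    surrogate = (unclipped * Tensor(take_unclipped.astype(float))
                 + clipped * Tensor((~take_unclipped).astype(float))).mean()
    entropy = -(logp_all.exp() * logp_all).sum(axis=1).mean()
    value_err = ((values - Tensor(batch["returns"])) ** 2.0).mean()
    objective = surrogate + config.c_entropy * entropy - config.c_value * value_err
    loss = -objective
    diagnostics = {
        "surrogate": float(surrogate.data),
        "entropy": float(entropy.data),
        "value_error": float(value_err.data),
        "clip_fraction": float(np.mean(np.abs(ratio.data - clipped_ratio) > 1e-12)),
    }
    return loss, diagnostics


def _collect_rollout(env: NutriEnv, policy: PolicyValueNet, config: PPOConfig,
                     rng: np.random.Generator):
    """Run whole episodes until at least ``config.rollout`` steps are
    gathered; GAE is applied per episode with a zero terminal bootstrap."""
    S, A, M, R, V, LP = [], [], [], [], [], []
    ADV, RET = [], []
    episode_rewards, terminal_components = [], []
    steps = 0
    while steps < config.rollout:
        state = env.reset()
        ep_states, ep_actions, ep_masks, ep_rewards, ep_values, ep_logp = \
            [], [], [], [], [], []
        ep_components = None
        done = False
        while not done:
            mask = env.action_mask(state)
            if not mask.any():
                break  # infeasible from the start
            x = featurize(state, env)
            logp, v = policy.forward_np(x[None, :], mask[None, :])
            p = np.exp(logp[0])
            p = p / p.sum()
            action = int(rng.choice(env.n_actions, p=p))
            outcome = env.step_state(state, action)
            ep_states.append(x)
            ep_actions.append(action)
            ep_masks.append(mask)
            ep_rewards.append(outcome.reward)
            ep_values.append(float(v[0]))
            ep_logp.append(float(logp[0, action]))
            ep_components = outcome.components
            state = outcome.next_state
            done = outcome.done
        if not ep_rewards:
            raise RuntimeError("environment has no feasible first action")
        adv, ret = gae(ep_rewards, np.array(ep_values + [0.0]),
                       config.gamma, config.lam)
        S += ep_states
        A += ep_actions
        M += ep_masks
        R += ep_rewards
        V += ep_values
        LP += ep_logp
        ADV += adv.tolist()
        RET += ret.tolist()
        episode_rewards.append(sum(ep_rewards))
        terminal_components.append(ep_components)
        steps += len(ep_rewards)
    traj = Trajectory(np.array(S), np.array(A), np.array(M), np.array(R),
                      np.array(V), np.array(LP), np.array(ADV), np.array(RET))
    return traj, episode_rewards, terminal_components


def train_ppo(env_factory, config: PPOConfig | None = None):
    """Train a masked policy with PPO; returns (policy, learning curve).

    ``env_factory`` is either a NutriEnv or a zero-argument callable
    producing one.  The curve records per-update mean episode reward, the
    mean terminal reward components, and loss diagnostics.
    """
    config = config or PPOConfig()
    env = env_factory() if callable(env_factory) else env_factory
    rng = np.random.default_rng(config.seed)
    state0 = env.reset()
    if not env.action_mask(state0).any():
        raise RuntimeError("environment has no feasible first action")
    n_features = len(featurize(state0, env))
    policy = PolicyValueNet(n_features, env.n_actions, config.hidden, config.seed)
    opt = Adam(policy.params(), lr=config.lr)
    rows = []
    for update in range(config.updates):
        traj, ep_rewards, terminal_components = _collect_rollout(
            env, policy, config, rng)
        n = len(traj.actions)
        diag_acc: dict[str, float] = {}
        n_batches = 0
        for _ in range(config.update_epochs):
            order = rng.permutation(n)
            for start in range(0, n, config.minibatch):
                idx = order[start:start + config.minibatch]
                batch = {
                    "states": traj.states[idx], "actions": traj.actions[idx],
                    "masks": traj.masks[idx], "log_probs": traj.log_probs[idx],
                    "advantages": traj.advantages[idx],
                    "returns": traj.returns[idx],
                }
                loss, diag = ppo_loss(batch, policy, config)
                if config.lr > 0:
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                for k, v in diag.items():
                    diag_acc[k] = diag_acc.get(k, 0.0) + v
                n_batches += 1
        comp_means = {f"terminal_{k}": float(np.mean([c[k] for c in terminal_components]))
                      for k in terminal_components[0]}
        row = {"update": update,
               "mean_episode_reward": float(np.mean(ep_rewards)),
               "n_episodes": len(ep_rewards),
               "upper_bound_violations": env.violations,
               **comp_means,
               **{k: v / n_batches for k, v in diag_acc.items()}}
        rows.append(row)
    return policy, pd.DataFrame(rows)


def recommend(policy: PolicyValueNet, profile: PatientProfile,
              food_db: list[FoodItem], horizon: int = 5,
              weights: RewardWeights | None = None) -> dict:
    """Greedy (argmax) masked decoding of a meal plan.

    Returns the ordered item list, nutrient totals, per-step reward
    components, and any shortfall against the guideline lower bounds.
    """
    env = NutriEnv(profile, food_db, horizon=horizon, weights=weights)
    state = env.reset()
    plan, components, total_reward = [], [], 0.0
    while state.t < horizon:
        mask = env.action_mask(state)
        if not mask.any():
            break
        x = featurize(state, env)
        logp, _ = policy.forward_np(x[None, :], mask[None, :])
        action = int(np.argmax(logp[0]))
        outcome = env.step_state(state, action)
        plan.append(food_db[action].id)
        components.append(outcome.components)
        total_reward += outcome.reward
        state = outcome.next_state
        if outcome.done:
            break
    totals = state.cumulative
    shortfall = np.maximum(0.0, profile.lower - totals)
    return {
        "plan": plan,
        "nutrient_totals": dict(zip(NUTRIENTS, totals.tolist())),
        "lower_bound_shortfall": dict(zip(NUTRIENTS, shortfall.tolist())),
        "total_reward": float(total_reward),
        "components": components,
    }
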