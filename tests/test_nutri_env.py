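"""Nutrition MDP: masking, reward terms, decomposition and safety."""

import numpy as np
import pytest

from cilad.datatypes import FoodItem, PatientProfile
from cilad.nutri_env import (NutriEnv, RewardWeights, adherence_term,
                             risk_term)


def toy_profile(**kw):
    base = dict(
        name="toy", age=50, bmi=25, risk=0.5,
        lower=np.zeros(5), upper=np.array([100.0, 10.0, 50.0, 100.0, 50.0]),
        targets=np.array([50.0, 5.0, 25.0, 50.0, 25.0]),
        tolerance=np.array([5.0, 1.0, 5.0, 5.0, 5.0]),
        hard_max=np.array([100.0, 10.0, 50.0, 100.0, 50.0]),
        risk_weights=np.ones(5))
    base.update(kw)
    return PatientProfile(**base)


def item(id_, nutrients, cost=1.0, tags=()):
    return FoodItem(id=id_, nutrients=tuple(nutrients), cost=cost,
                    tags=frozenset(tags))


class TestRewardTerms:
    def test_adherence_zero_within_tolerance(self):
        assert adherence_term([50, 5, 25, 50, 25], [50, 5, 25, 50, 25],
                              [1, 1, 1, 1, 1]) == 0.0

    def test_adherence_forced_value_1d(self):
        # d=1, deviation = T + 2 -> -(2^2)/1 = -4
        assert adherence_term([10.0], [5.0], [3.0]) == pytest.approx(-4.0)

    def test_adherence_matches_loop_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            c, g, T = rng.normal(5, 2, (3, 5))
            T = np.abs(T)
            expected = -sum(max(0.0, abs(ci - gi) - Ti) ** 2
                            for ci, gi, Ti in zip(c, g, T)) / 5
            assert adherence_term(c, g, T) == pytest.approx(expected, abs=1e-12)

    def test_risk_zero_below_max_and_forced_value(self):
        assert risk_term([1, 1, 1, 1, 1], [2, 2, 2, 2, 2], np.ones(5)) == 0.0
        # one nutrient exceeds by 3 with weight 2 -> -18
        assert risk_term([5, 0, 0, 0, 0], [2, 2, 2, 2, 2],
                         [2, 1, 1, 1, 1]) == pytest.approx(-18.0)

    def test_risk_matches_loop_oracle(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            c = rng.uniform(0, 10, 5)
            gmax = rng.uniform(0, 10, 5)
            w = rng.uniform(0, 3, 5)
            expected = -sum(wi * max(0.0, ci - gi) ** 2
                            for ci, gi, wi in zip(c, gmax, w))
            assert risk_term(c, gmax, w) == pytest.approx(expected, abs=1e-12)


class TestFeasibility:
    def test_hand_enumerated_toy_db(self):
        profile = toy_profile(exclusions=frozenset({"banned"}),
                              forbidden_tags=frozenset({"fried"}))
        db = [
            item("ok_small", [10, 1, 2, 10, 2]),
            item("too_much_sodium", [150, 0, 0, 0, 0]),
            item("banned", [1, 0, 0, 1, 0]),
            item("fried_thing", [5, 1, 0, 20, 5], tags=("fried",)),
            item("ok_big", [90, 9, 40, 90, 40]),
        ]
        env = NutriEnv(profile, db, horizon=3)
        feasible = env.feasible_actions(env.reset())
        assert feasible.tolist() == [0, 4]  # by hand: sodium cap, exclusion, tag

    def test_sodium_budget_masks_when_exhausted(self):
        profile = toy_profile()
        db = [item("salty", [60, 0, 0, 0, 0]), item("plain", [0, 0, 1, 1, 0])]
        env = NutriEnv(profile, db, horizon=4)
        s = env.reset()
        out = env.step_state(s, 0)  # sodium 60/100
        feasible = env.feasible_actions(out.next_state)
        assert feasible.tolist() == [1]  # another salty item would break 100

    def test_infeasible_set_terminates_not_raises(self):
        profile = toy_profile()
        db = [item("big", [80, 0, 0, 0, 0])]
        env = NutriEnv(profile, db, horizon=5)
        out = env.step_state(env.reset(), 0)
        assert out.done and out.infeasible


class TestStep:
    def test_zero_weights_zero_reward(self, food_db, hypertension_profile):
        w = RewardWeights(alpha=0, beta=0, gamma_pref=0, delta_div=0, eta_cost=0)
        env = NutriEnv(hypertension_profile, food_db, horizon=5, weights=w)
        s = env.reset()
        out = env.step_state(s, int(env.feasible_actions(s)[0]))
        assert out.reward == 0.0

    def test_reward_equals_weighted_component_sum(self, food_db,
                                                  hypertension_profile):
        rng = np.random.default_rng(0)
        w = RewardWeights(alpha=1.2, beta=0.7, gamma_pref=0.4, delta_div=0.6,
                          eta_cost=0.2)
        env = NutriEnv(hypertension_profile, food_db, horizon=5, weights=w)
        state = env.reset()
        for _ in range(5):
            feas = env.feasible_actions(state)
            if len(feas) == 0:
                break
            out = env.step_state(state, int(rng.choice(feas)))
            recombined = (w.alpha * out.components["adherence"]
                          + w.beta * out.components["risk"]
                          + w.gamma_pref * out.components["preference"]
                          + w.delta_div * out.components["diversity"]
                          + w.eta_cost * out.components["cost"])
            assert out.reward == pytest.approx(recombined, abs=1e-12)
            state = out.next_state
            if out.done:
                break

    def test_cumulative_is_sum_of_chosen_items(self, food_db,
                                               hypertension_profile):
        env = NutriEnv(hypertension_profile, food_db, horizon=5)
        state = env.reset()
        chosen = []
        for _ in range(5):
            feas = env.feasible_actions(state)
            a = int(feas[0])
            chosen.append(food_db[a].nutrient_array)
            out = env.step_state(state, a)
            state = out.next_state
            if out.done:
                break
        assert np.allclose(state.cumulative, np.sum(chosen, axis=0), atol=1e-9)

    def test_infeasible_action_is_contract_violation(self, food_db):
        profile = toy_profile(exclusions=frozenset({food_db[0].id}))
        env = NutriEnv(profile, food_db, horizon=5)
        with pytest.raises(ValueError, match="mask"):
            env.step_state(env.reset(), 0)

    def test_diversity_counts_repeats(self):
        profile = toy_profile()
        db = [item("x", [1, 0.1, 1, 1, 1], cost=0.0)]
        env = NutriEnv(profile, db, horizon=3, weights=RewardWeights(rho=0.5))
        s = env.reset()
        o1 = env.step_state(s, 0)
        o2 = env.step_state(o1.next_state, 0)
        o3 = env.step_state(o2.next_state, 0)
        assert o1.components["diversity"] == 0.0
        assert o2.components["diversity"] == pytest.approx(-0.5)
        assert o3.components["diversity"] == pytest.approx(-1.0)
        assert o3.components["cost"] == 0.0  # free item

    def test_preference_violation_penalty(self):
        profile = toy_profile(required_tags=frozenset({"vegetarian"}))
        db = [item("meat", [1, 1, 0, 10, 5]),
              item("veg", [1, 0, 2, 10, 0], tags=("vegetarian",))]
        env = NutriEnv(profile, db, horizon=2,
                       weights=RewardWeights(lambda_viol=2.0))
        s = env.reset()
        assert env.step_state(s, 0).components["preference"] == -2.0
        assert env.step_state(s, 1).components["preference"] == 1.0


class TestInvariants:
    def test_reset_state(self, food_db, hypertension_profile):
        env = NutriEnv(hypertension_profile, food_db, horizon=5)
        s = env.reset()
        assert np.all(s.cumulative == 0) and s.t == 0 and s.history == ()
        with pytest.raises(ValueError):
            NutriEnv(hypertension_profile, food_db, horizon=0)

    def test_masked_rollouts_never_violate_upper_bounds(self, food_db,
                                                        hypertension_profile):
        rng = np.random.default_rng(123)
        env = NutriEnv(hypertension_profile, food_db, horizon=5)
        for _ in range(10_000):
            state = env.reset()
            prev = state.cumulative
            while True:
                feas = env.feasible_actions(state)
                if len(feas) == 0 or state.t >= env.horizon:
                    break
                out = env.step_state(state, int(rng.choice(feas)))
                state = out.next_state
                assert np.all(state.cumulative <= env.profile.upper + 1e-9)
                assert np.all(state.cumulative >= prev - 1e-12)  # nondecreasing
                prev = state.cumulative
                if out.done:
                    break
        assert env.violations == 0
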