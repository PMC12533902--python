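"""The nutrition-recommendation MDP: state, feasible-action masking and the
five-component reward (adherence, risk, preference, diversity, cost).

Hard guideline upper bounds are enforced through the action mask, so no
masked trajectory can ever exceed them; the guideline lower bounds are
enforced as a terminal shortfall penalty folded into the adherence
component (enforcing them per step would deadlock the first meal of the
day).  Adherence and risk are computed on guideline-normalized nutrient
units (intake divided by the per-nutrient target) so the penalties are
dimensionless and comparable across nutrients; the per-step adherence
target is pro-rated over the horizon, with the full daily target applied at
the terminal step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datatypes import NUTRIENTS, FoodItem, PatientProfile


@dataclass
class RewardWeights:
    """Mixing weights of the multi-objective reward and its penalty scales."""

    alpha: float = 1.0        # adherence
    beta: float = 1.0         # risk
    gamma_pref: float = 0.5   # preference
    delta_div: float = 0.3    # diversity
    eta_cost: float = 0.1     # cost
    lambda_viol: float = 1.0  # preference-violation penalty
    rho: float = 0.5          # repetition penalty per prior occurrence
    kappa_cost: float = 0.05  # cost coefficient (per currency unit)

    def __post_init__(self) -> None:
        for name in ("alpha", "beta", "gamma_pref", "delta_div", "eta_cost",
                     "lambda_viol", "rho", "kappa_cost"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")


@dataclass
class NutriState:
    profile: PatientProfile
    cumulative: np.ndarray          # c_t, nutrient intake so far
    t: int
    history: tuple[int, ...]        # chosen action indices

    def __post_init__(self) -> None:
        self.cumulative = np.asarray(self.cumulative, dtype=float)


@dataclass
class StepOutcome:
    next_state: NutriState
    reward: float
    components: dict[str, float]
    done: bool
    infeasible: bool = False  # episode ended because no action was feasible


# --------------------------------------------------------------------------
# Reward terms
# --------------------------------------------------------------------------

def adherence_term(c, g, T) -> float:
    """-(1/d) * sum_i max(0, |c_i - g_i| - T_i)^2 (nonpositive)."""
    c = np.asarray(c, dtype=float)
    g = np.asarray(g, dtype=float)
    T = np.asarray(T, dtype=float)
    over = np.maximum(0.0, np.abs(c - g) - T)
    return float(-np.mean(over ** 2))


def risk_term(c, g_max, w_risk) -> float:
    """-sum_i w_i * max(0, c_i - g_max_i)^2 (nonpositive)."""
    c = np.asarray(c, dtype=float)
    over = np.maximum(0.0, c - np.asarray(g_max, dtype=float))
    return float(-(np.asarray(w_risk, dtype=float) * over ** 2).sum())


def soft_terms(item: FoodItem, state: NutriState, weights: RewardWeights,
               action_index: int) -> dict[str, float]:
    """Preference (+1 / -lambda_viol), diversity (-rho * repeat count) and
    cost (-kappa * Cost) components of the reward."""
    profile = state.profile
    prefs_ok = (profile.required_tags <= item.tags
                and not (profile.forbidden_tags & item.tags))
    preference = 1.0 if prefs_ok else -weights.lambda_viol
    repeats = state.history.count(action_index)
    diversity = -weights.rho * repeats
    cost = -weights.kappa_cost * item.cost
    return {"preference": preference, "diversity": diversity, "cost": cost}


# --------------------------------------------------------------------------
# Environment
# --------------------------------------------------------------------------

class NutriEnv:
    """Sequential meal recommendation over a discrete food database.

    Functional core (``feasible_actions`` / ``step_state``) plus a small
    stateful reset/step wrapper in the conventional RL shape.
    """

    def __init__(self, profile: PatientProfile, food_db: list[FoodItem],
                 horizon: int = 5, weights: RewardWeights | None = None,
                 seed: int = 0):
        if horizon <= 0:
            raise ValueError("horizon must be positive")
        if not food_db:
            raise ValueError("food database is empty")
        self.profile = profile
        self.food_db = list(food_db)
        self.horizon = int(horizon)
        self.weights = weights or RewardWeights()
        self.seed = seed
        self._nutrients = np.stack([f.nutrient_array for f in self.food_db])
        # guideline-normalization scale: the per-nutrient target (fallback 1)
        g = profile.targets.copy()
        g[g == 0] = 1.0
        self._scale = g
        self.n_actions = len(self.food_db)
        self.state: NutriState | None = None
        self.violations = 0  # upper-bound violations observed (must stay 0)

    # -- functional core ----------------------------------------------------
    def reset(self) -> NutriState:
        self.state = NutriState(self.profile, np.zeros(len(NUTRIENTS)), 0, ())
        return self.state

    def feasible_actions(self, state: NutriState) -> np.ndarray:
        """Indices a with c_t + n(a) <= u, a not excluded, and no forbidden
        tag; an empty result signals terminal infeasibility, not an error."""
        ok = np.all(state.cumulative[None, :] + self._nutrients
                    <= self.profile.upper[None, :] + 1e-9, axis=1)
        for i, item in enumerate(self.food_db):
            if item.id in self.profile.exclusions:
                ok[i] = False
            elif self.profile.forbidden_tags & item.tags:
                ok[i] = False
        return np.flatnonzero(ok)

    def action_mask(self, state: NutriState) -> np.ndarray:
        mask = np.zeros(self.n_actions, dtype=bool)
        mask[self.feasible_actions(state)] = True
        return mask

    def _prorated_target(self, steps_done: int) -> np.ndarray:
        return self.profile.targets * steps_done / self.horizon

    def step_state(self, state: NutriState, action: int) -> StepOutcome:
        """Apply one action; the caller must respect the mask."""
        if action not in self.feasible_actions(state):
            raise ValueError(f"action {action} violates the feasibility mask")
        item = self.food_db[action]
        w = self.weights
        c_next = state.cumulative + item.nutrient_array
        t_next = state.t + 1
        next_state = NutriState(state.profile, c_next, t_next,
                                state.history + (action,))
        if np.any(c_next > self.profile.upper + 1e-9):  # mask guarantee
            self.violations += 1
        terminal_by_horizon = t_next >= self.horizon
        infeasible = (not terminal_by_horizon
                      and len(self.feasible_actions(next_state)) == 0)
        done = terminal_by_horizon or infeasible

        g_step = (self.profile.targets if done else self._prorated_target(t_next))
        adherence = adherence_term(c_next / self._scale, g_step / self._scale,
                                   self.profile.tolerance / self._scale)
        if done:
            shortfall = np.maximum(0.0, (self.profile.lower - c_next) / self._scale)
            adherence += float(-np.mean(shortfall ** 2))
        risk = risk_term(c_next / self._scale, self.profile.hard_max / self._scale,
                         self.profile.risk_weights)
        soft = soft_terms(item, state, w, action)
        components = {"adherence": adherence, "risk": risk, **soft}
        reward = (w.alpha * components["adherence"] + w.beta * components["risk"]
                  + w.gamma_pref * components["preference"]
                  + w.delta_div * components["diversity"]
                  + w.eta_cost * components["cost"])
        return StepOutcome(next_state, float(reward), components, done, infeasible)

    # -- stateful wrapper ---------------------------------------------------
    def step(self, action: int) -> StepOutcome:
        if self.state is None:
            raise RuntimeError("call reset() before step()")
        outcome = self.step_state(self.state, action)
        self.state = outcome.next_state
        return outcome


def reset(profile: PatientProfile, food_db: list[FoodItem], horizon: int,
          seed: int = 0) -> tuple[NutriEnv, NutriState]:
    """Build an environment and return it with its initial state."""
    env = NutriEnv(profile, food_db, horizon=horizon, seed=seed)
    return env, env.reset()
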