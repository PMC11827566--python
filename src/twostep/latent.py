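"""Latent-state arithmetic of the hybrid models, spelled out step by step.

This module is the readable reference implementation of the model equations:
SARSA value updates with credit assignment of the second-stage prediction
error to the first stage, forgetting of unchosen values toward the mid-range
0.5, Bellman-weighted model-based values, the habitual controller, and the
two counter-based exploration bonuses.  The numba kernels in
:mod:`twostep._core` implement the same recursions for speed; the two paths
are held equal by tests.

All rewards entering these updates are on the unit scale (magnitude-variant
rewards divided by 100), so the forgetting target 0.5 is the mid-range of
the value scale and Q values stay within [0, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .variants import ModelVariant, ParameterSet, get_variant

#: global option index for (s2_state, s2_action): B0, B1, C0, C1
def option_index(s2_state: int, s2_action: int) -> int:
    return 2 * s2_state + s2_action


@dataclass
class LatentState:
    """Per-trial agent state.

    ``bandit_sets[n]`` holds which *other* options were sampled since option
    ``n`` was last chosen (so the bandit counter is its size, at most 3);
    ``trial_count[n]`` counts trials since option ``n`` was last sampled,
    starting at 1 so that ``ln(count)`` starts at 0.
    """

    q_mf_s1: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))
    q2: np.ndarray = field(default_factory=lambda: np.full((2, 2), 0.5))
    habit: np.ndarray = field(default_factory=lambda: np.zeros(2))
    bandit_sets: list = field(default_factory=lambda: [set(), set(), set(), set()])
    trial_count: np.ndarray = field(default_factory=lambda: np.ones(4, dtype=int))
    prev_s1_action: int | None = None

    @property
    def bandit_count(self) -> np.ndarray:
        return np.array([min(len(s), 3) for s in self.bandit_sets], dtype=int)


def init_latent_state(variant: ModelVariant | str | None = None) -> LatentState:
    """Neutral starting state: all Q at the forgetting fixed point 0.5,
    habits at 0, bandit counters empty, trial counters at 1."""
    return LatentState()


def _transition_prob_to_state0(s1_action: int, common0: int, p_common: float) -> float:
    common = common0 if s1_action == 0 else 1 - common0
    return p_common if common == 0 else 1.0 - p_common


def mb_values(state: LatentState, common0: int = 0, p_common: float = 0.7) -> np.ndarray:
    """Bellman values: per action, transition-probability-weighted maxima of
    the second-stage Q values."""
    max_q = state.q2.max(axis=1)
    out = np.empty(2)
    for a in range(2):
        p0 = _transition_prob_to_state0(a, common0, p_common)
        out[a] = p0 * max_q[0] + (1.0 - p0) * max_q[1]
    return out


def _weighted_state_sums(per_state: np.ndarray, common0: int, p_common: float) -> np.ndarray:
    out = np.empty(2)
    for a in range(2):
        p0 = _transition_prob_to_state0(a, common0, p_common)
        out[a] = p0 * per_state[0] + (1.0 - p0) * per_state[1]
    return out


def exploration_bonus_bandit(state: LatentState, common0: int = 0,
                             p_common: float = 0.7) -> np.ndarray:
    """Bandit-counter bonus: per-state sums of options-sampled-since counters,
    weighted by the transition probabilities (range [0, 6])."""
    b = state.bandit_count
    per_state = np.array([b[0] + b[1], b[2] + b[3]], dtype=float)
    return _weighted_state_sums(per_state, common0, p_common)


def exploration_bonus_trial(state: LatentState, common0: int = 0,
                            p_common: float = 0.7) -> np.ndarray:
    """Trial-counter bonus: per-option max(0, ln t), summed per state and
    transition-weighted like the bandit bonus."""
    t = state.trial_count
    if np.any(t < 1):
        raise ValueError("trial counters must be >= 1")
    logs = np.maximum(0.0, np.log(t.astype(float)))
    per_state = np.array([logs[0] + logs[1], logs[2] + logs[3]])
    return _weighted_state_sums(per_state, common0, p_common)


def _softmax2(u: np.ndarray) -> np.ndarray:
    m = u.max()
    e = np.exp(u - m)
    return e / e.sum()


def s1_utilities(state: LatentState, params: ParameterSet, variant: ModelVariant,
                 common0: int = 0, p_common: float = 0.7) -> np.ndarray:
    variant = get_variant(variant)
    vec = params.as_vector(variant)
    qmb = mb_values(state, common0, p_common)
    if variant.uses_hop:
        pers = state.habit.copy()
    else:
        pers = np.zeros(2)
        if state.prev_s1_action is not None:
            pers[state.prev_s1_action] = 1.0
    u = vec[4] * qmb + vec[5] * state.q_mf_s1 + vec[6] * pers
    if variant.exploration == "bandit":
        u = u + vec[8] * exploration_bonus_bandit(state, common0, p_common)
    elif variant.exploration == "trial":
        u = u + vec[8] * exploration_bonus_trial(state, common0, p_common)
    return u


def s1_probabilities(state: LatentState, params: ParameterSet,
                     variant: ModelVariant | str, common0: int = 0,
                     p_common: float = 0.7) -> np.ndarray:
    """First-stage SoftMax over model-based, model-free, perseveration and
    (optionally) exploration-bonus terms."""
    return _softmax2(s1_utilities(state, params, get_variant(variant), common0, p_common))


def s2_probabilities(state: LatentState, s2_state: int,
                     params: ParameterSet) -> np.ndarray:
    """Second-stage SoftMax over beta2-scaled Q2 values of the visited state."""
    beta2 = params.beta2 if params.beta2 is not None else 0.0
    return _softmax2(beta2 * state.q2[s2_state])


_S2_LABELS = {"B": 0, "C": 1, 0: 0, 1: 1}


def update_state(state: LatentState, record: Mapping, params: ParameterSet,
                 variant: ModelVariant | str, decay_all: bool = False) -> LatentState:
    """Advance the latent state by one trial (in place; also returned).

    ``record`` needs keys ``s1_action``, ``s2_state`` (``'B'``/``'C'`` or
    0/1), ``s2_action``, ``reward`` (unit scale) and optionally ``valid``.
    Invalid trials advance only the sampling counters: value and habit
    updates, and the perseveration reference, are skipped.
    """
    variant = get_variant(variant)
    vec = params.as_vector(variant)
    a1, a2lr, a3, ahop = vec[0], vec[1], vec[2], vec[3]
    c1 = int(record["s1_action"])
    s2 = _S2_LABELS[record["s2_state"]]
    ca2 = int(record["s2_action"])
    valid = bool(record.get("valid", True))

    if valid:
        r = float(record["reward"])
        if not (0.0 <= r <= 1.0):
            raise ValueError("reward must be on the unit scale [0, 1]")
        delta1 = state.q2[s2, ca2] - state.q_mf_s1[c1]
        state.q_mf_s1[c1] += a1 * delta1
        delta2 = r - state.q2[s2, ca2]
        state.q2[s2, ca2] += a2lr * delta2
        state.q_mf_s1[c1] += a2lr * delta2
        state.q_mf_s1[1 - c1] = a3 * state.q_mf_s1[1 - c1] + (1 - a3) * 0.5
        state.q2[s2, 1 - ca2] = a3 * state.q2[s2, 1 - ca2] + (1 - a3) * 0.5
        if decay_all:
            state.q2[1 - s2, :] = a3 * state.q2[1 - s2, :] + (1 - a3) * 0.5
        if variant.uses_hop:
            rep = np.zeros(2)
            rep[c1] = 1.0
            state.habit += ahop * (rep - state.habit)
        state.prev_s1_action = c1

    n = option_index(s2, ca2)
    state.bandit_sets[n] = set()
    state.trial_count[n] = 1
    for m in range(4):
        if m != n:
            state.bandit_sets[m].add(n)
            state.trial_count[m] += 1
    return state


def sequence_loglik_reference(s1, s2, a2, reward, valid, params: ParameterSet,
                              variant: ModelVariant, common0: int = 0,
                              p_common: float = 0.7, decay_all: bool = False):
    """Trial-by-trial log-likelihood via the reference ops (slow path).

    Arrays use integer state coding and unit-scale rewards.  Returns
    ``(total, pointwise)`` with one pointwise entry per valid trial.
    """
    variant = get_variant(variant)
    state = init_latent_state(variant)
    pointwise = []
    for t in range(len(s1)):
        if valid[t]:
            p1 = s1_probabilities(state, params, variant, common0, p_common)
            p2 = s2_probabilities(state, int(s2[t]), params)
            pointwise.append(math.log(p1[s1[t]]) + math.log(p2[a2[t]]))
        update_state(state,
                     dict(s1_action=s1[t], s2_state=int(s2[t]),
                          s2_action=a2[t], reward=reward[t], valid=bool(valid[t])),
                     params, variant, decay_all=decay_all)
    pointwise = np.asarray(pointwise)
    return float(pointwise.sum()), pointwise
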