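"""Latent-state arithmetic: value updates, bonuses, choice rules, likelihood."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from twostep.latent import (LatentState, exploration_bonus_bandit,
                            exploration_bonus_trial, init_latent_state,
                            mb_values, s1_probabilities, s2_probabilities,
                            update_state)
from twostep.likelihood import sequence_loglik
from twostep.task import TaskConfig, simulate_agent
from twostep.variants import ParameterSet, get_variant


class TestInitialState:
    def test_first_trial_choice_probabilities_are_uniform(self, hop_params, fop_params):
        for variant, params in (("q_hop", hop_params), ("q_fop", fop_params)):
            state = init_latent_state(variant)
            assert np.allclose(s1_probabilities(state, params, variant), [0.5, 0.5])

    def test_initial_bonuses_are_zero(self):
        state = init_latent_state()
        assert np.allclose(exploration_bonus_bandit(state), 0.0)
        assert np.allclose(exploration_bonus_trial(state), 0.0)


class TestModelBasedValues:
    def test_hand_worked_bellman_values(self):
        state = init_latent_state()
        state.q2 = np.array([[1.0, 0.0], [0.0, 0.5]])  # B, C
        np.testing.assert_allclose(mb_values(state, common0=0, p_common=0.7),
                                   [0.85, 0.65])

    def test_constant_field_gives_equal_values(self):
        state = init_latent_state()
        state.q2 = np.full((2, 2), 0.37)
        np.testing.assert_allclose(mb_values(state), [0.37, 0.37])

    def test_swapping_mapping_swaps_values(self):
        state = init_latent_state()
        state.q2 = np.array([[0.9, 0.1], [0.2, 0.6]])
        a = mb_values(state, common0=0)
        b = mb_values(state, common0=1)
        np.testing.assert_allclose(a, b[::-1])


class TestExplorationBonuses:
    def test_bandit_bonus_saturates_at_six(self):
        state = init_latent_state()
        # every option's distinct-alternatives set is full (3 others sampled)
        state.bandit_sets = [{1, 2, 3}, {0, 2, 3}, {0, 1, 3}, {0, 1, 2}]
        np.testing.assert_allclose(exploration_bonus_bandit(state), [6.0, 6.0])

    def test_bandit_bonus_hand_worked(self):
        state = init_latent_state()
        state.bandit_sets = [{1, 2, 3}, {0, 2, 3}, set(), set()]  # b = (3,3,0,0)
        np.testing.assert_allclose(exploration_bonus_bandit(state, common0=0),
                                   [4.2, 1.8])

    def test_trial_bonus_hand_worked(self):
        state = init_latent_state()
        state.trial_count = np.array([math.e, math.e, 1.0, 1.0])
        np.testing.assert_allclose(exploration_bonus_trial(state, common0=0),
                                   [1.4, 0.6])

    def test_trial_bonus_monotone_in_counters(self, rng):
        state = init_latent_state()
        state.trial_count = rng.integers(1, 50, size=4).astype(float)
        base = exploration_bonus_trial(state)
        for n in range(4):
            bumped = init_latent_state()
            bumped.trial_count = state.trial_count.copy()
            bumped.trial_count[n] += 1
            assert (exploration_bonus_trial(bumped) >= base - 1e-12).all()


class TestChoiceRules:
    def test_closed_form_two_option_softmax(self):
        state = init_latent_state()
        # engineer Q_MB = (0.8, 0.2): with common0=0, p=0.7 need
        # 0.7*maxB + 0.3*maxC = 0.8 and 0.3*maxB + 0.7*maxC = 0.2
        state.q2 = np.array([[1.25, 0.0], [-0.25, -1.0]])
        params = ParameterSet(alpha1=0.5, alpha2=0.5, alpha3=0.5,
                              beta_mb=2.0, beta_mf=0.0, beta_persev=0.0,
                              beta2=0.0)
        p = s1_probabilities(state, params, "q_fop")
        assert p[0] == pytest.approx(1.0 / (1.0 + math.exp(-2.0 * 0.6)), abs=1e-5)
        assert p[0] == pytest.approx(0.76852, abs=1e-4)

    def test_s2_softmax_closed_form_and_shift_invariance(self):
        state = init_latent_state()
        state.q2 = np.array([[1.0, 0.0], [0.0, 0.0]])
        params = ParameterSet(beta2=1.0)
        p = s2_probabilities(state, 0, params)
        assert p[0] == pytest.approx(1.0 / (1.0 + math.exp(-1.0)), abs=1e-6)
        state.q2[0] += 3.21
        np.testing.assert_allclose(s2_probabilities(state, 0, params), p)

    def test_beta2_zero_gives_uniform(self):
        state = init_latent_state()
        state.q2 = np.array([[0.9, 0.1], [0.5, 0.5]])
        np.testing.assert_allclose(
            s2_probabilities(state, 0, ParameterSet(beta2=0.0)), [0.5, 0.5])

    def test_hop_with_unit_step_equals_fop_after_one_update(self, hop_params, fop_params):
        record = dict(s1_action=0, s2_state=0, s2_action=1, reward=0.7)
        hop1 = ParameterSet(**{**hop_params.to_dict(), "alpha_hop": 1.0 - 1e-12})
        s_hop = update_state(init_latent_state(), record, hop1, "q_hop")
        s_fop = update_state(init_latent_state(), record, fop_params, "q_fop")
        np.testing.assert_allclose(
            s1_probabilities(s_hop, hop1, "q_hop"),
            s1_probabilities(s_fop, fop_params, "q_fop"), atol=1e-10)

    def test_perseveration_weight_increases_repeat_probability(self, fop_params):
        record = dict(s1_action=1, s2_state=1, s2_action=0, reward=0.4)
        probs = []
        for bp in (0.0, 0.5, 1.5, 3.0):
            p = ParameterSet(**{**fop_params.to_dict(), "beta_persev": bp})
            state = update_state(init_latent_state(), record, p, "q_fop")
            probs.append(s1_probabilities(state, p, "q_fop")[1])
        assert np.all(np.diff(probs) > 0)


class TestStateUpdate:
    def test_zero_learning_rates_leave_values_untouched(self):
        params = ParameterSet(alpha1=1e-12, alpha2=1e-12, alpha3=1.0 - 1e-12,
                              alpha_hop=1e-12, beta_mb=1.0, beta_mf=1.0,
                              beta_persev=1.0, beta2=1.0)
        state = update_state(init_latent_state(),
                             dict(s1_action=0, s2_state=0, s2_action=0, reward=1.0),
                             params, "q_hop")
        np.testing.assert_allclose(state.q_mf_s1, 0.5, atol=1e-9)
        np.testing.assert_allclose(state.q2, 0.5, atol=1e-9)
        np.testing.assert_allclose(state.habit, 0.0, atol=1e-9)
        assert state.prev_s1_action == 0
        assert state.trial_count.tolist() == [1, 2, 2, 2]

    def test_habit_update_hand_worked(self):
        params = ParameterSet(alpha1=0.1, alpha2=0.1, alpha3=0.9, alpha_hop=0.5,
                              beta_mb=0.0, beta_mf=0.0, beta_persev=0.0, beta2=0.0)
        state = update_state(init_latent_state(),
                             dict(s1_action=0, s2_state=0, s2_action=0, reward=0.5),
                             params, "q_hop")
        np.testing.assert_allclose(state.habit, [0.5, 0.0])

    def test_bandit_counter_reaches_three_after_other_options_sampled(self, fop_params):
        state = init_latent_state()
        # option 0 (= B action 0) sampled, then the other three, with repeats
        for s2, a2 in [(0, 0), (0, 1), (1, 0), (1, 0), (1, 1), (0, 1)]:
            update_state(state, dict(s1_action=0, s2_state=s2, s2_action=a2,
                                     reward=0.5), fop_params, "q_fop")
        assert state.bandit_count[0] == 3

    def test_second_stage_values_stay_in_unit_interval(self, rng, fop_params):
        """Q2 updates are convex combinations of values in [0, 1], so Q2 is
        bounded.  (The first-stage MF values are not: the stage-2
        prediction-error transfer can push them outside the unit interval,
        so no such assertion is made for them.)"""
        state = init_latent_state()
        for _ in range(200):
            rec = dict(s1_action=int(rng.integers(2)),
                       s2_state=int(rng.integers(2)),
                       s2_action=int(rng.integers(2)),
                       reward=float(rng.random()))
            update_state(state, rec, fop_params, "q_fop")
            assert (0.0 <= state.q2).all() and (state.q2 <= 1.0).all()
            assert (0.0 <= state.habit).all() and (state.habit <= 1.0).all()

    def test_out_of_range_reward_rejected(self, fop_params):
        with pytest.raises(ValueError):
            update_state(init_latent_state(),
                         dict(s1_action=0, s2_state=0, s2_action=0, reward=1.5),
                         fop_params, "q_fop")


def _three_trial_table():
    return pd.DataFrame({
        "subject": "s1",
        "trial": [1, 2, 3],
        "s1_action": [0, 1, 0],
        "transition": ["common", "rare", "common"],
        "s2_state": ["B", "B", "B"],
        "s2_action": [1, 0, 1],
        "reward": [80.0, 20.0, 60.0],
        "rt_ms": np.nan,
        "valid": True,
    })


def _oracle_three_trial_loglik():
    """Brute-force scalar trace of the 3-trial example (Q+FOP, all rates
    one-half except full decay, unit SoftMax weights)."""
    p = 0.7
    qmf = [0.5, 0.5]
    q2 = {("B", 0): 0.5, ("B", 1): 0.5, ("C", 0): 0.5, ("C", 1): 0.5}
    prev = None
    total = 0.0
    for (a1, s2s, a2, r) in [(0, "B", 1, 0.8), (1, "B", 0, 0.2), (0, "B", 1, 0.6)]:
        maxB = max(q2[("B", 0)], q2[("B", 1)])
        maxC = max(q2[("C", 0)], q2[("C", 1)])
        qmb0 = p * maxB + (1 - p) * maxC          # action 0 common -> B
        qmb1 = (1 - p) * maxB + p * maxC
        u0 = qmb0 + qmf[0] + (1.0 if prev == 0 else 0.0)
        u1 = qmb1 + qmf[1] + (1.0 if prev == 1 else 0.0)
        p1 = math.exp(u0) / (math.exp(u0) + math.exp(u1))
        p_a1 = p1 if a1 == 0 else 1 - p1
        v0, v1 = q2[(s2s, 0)], q2[(s2s, 1)]
        p2 = math.exp(v0) / (math.exp(v0) + math.exp(v1))
        p_a2 = p2 if a2 == 0 else 1 - p2
        total += math.log(p_a1) + math.log(p_a2)
        # updates: alpha1 = alpha2 = 0.5, alpha3 = 1 (no decay)
        d1 = q2[(s2s, a2)] - qmf[a1]
        qmf[a1] += 0.5 * d1
        d2 = r - q2[(s2s, a2)]
        q2[(s2s, a2)] += 0.5 * d2
        qmf[a1] += 0.5 * d2
        prev = a1
    return total


class TestSequenceLoglik:
    def test_single_trial_uniform_policy(self, mag_config):
        tab = _three_trial_table().iloc[[0]]
        params = ParameterSet(alpha1=0.5, alpha2=0.5, alpha3=0.5, beta_mb=0.0,
                              beta_mf=0.0, beta_persev=0.0, beta2=0.0)
        total, pw = sequence_loglik(tab, params, "q_fop", mag_config)
        assert total == pytest.approx(2 * math.log(0.5), abs=1e-12)
        assert len(pw) == 1

    def test_three_trial_trace_matches_independent_oracle(self, mag_config):
        params = ParameterSet(alpha1=0.5, alpha2=0.5, alpha3=1.0 - 1e-15,
                              beta_mb=1.0, beta_mf=1.0, beta_persev=1.0,
                              beta2=1.0)
        total, _ = sequence_loglik(_three_trial_table(), params, "q_fop",
                                   mag_config)
        assert total == pytest.approx(_oracle_three_trial_loglik(), abs=1e-10)

    def test_fast_and_reference_engines_agree(self, mag_config, hop_params):
        tab = simulate_agent(mag_config.with_trials(80), "q_hop", hop_params, seed=5)
        t1, p1 = sequence_loglik(tab, hop_params, "q_hop", mag_config.with_trials(80))
        t2, p2 = sequence_loglik(tab, hop_params, "q_hop",
                                 mag_config.with_trials(80), engine="reference")
        assert t1 == pytest.approx(t2, abs=1e-10)
        np.testing.assert_allclose(p1, p2, atol=1e-12)

    @pytest.mark.parametrize("explo_variant,base_variant",
                             [("q_bandit", "q_fop"), ("q_trial", "q_fop"),
                              ("q_bandit_hop", "q_hop"), ("q_trial_hop", "q_hop")])
    def test_zero_exploration_weight_reduces_to_base_model(
            self, mag_config, hop_params, fop_params, explo_variant, base_variant):
        base = hop_params if get_variant(explo_variant).uses_hop else fop_params
        tab = simulate_agent(mag_config.with_trials(120), base_variant, base, seed=8)
        ext = ParameterSet(**{**base.to_dict(), "phi": 0.0})
        t_ext, _ = sequence_loglik(tab, ext, explo_variant, mag_config.with_trials(120))
        t_base, _ = sequence_loglik(tab, base, base_variant, mag_config.with_trials(120))
        assert t_ext == t_base

    def test_hop_with_unit_step_equals_fop_exactly(self, mag_config, fop_params):
        tab = simulate_agent(mag_config.with_trials(150), "q_fop", fop_params, seed=12)
        hop = ParameterSet(**{**fop_params.to_dict(), "alpha_hop": 1.0 - 1e-16})
        t_fop, _ = sequence_loglik(tab, fop_params, "q_fop", mag_config.with_trials(150))
        t_hop, _ = sequence_loglik(tab, hop, "q_hop", mag_config.with_trials(150))
        assert t_hop == pytest.approx(t_fop, abs=1e-9)

    def test_invalid_trials_excluded_from_pointwise(self, mag_config, fop_params):
        tab = simulate_agent(mag_config.with_trials(50), "q_fop", fop_params, seed=3)
        tab.loc[tab.index[10:15], "valid"] = False
        _, pw = sequence_loglik(tab, fop_params, "q_fop", mag_config.with_trials(50))
        assert len(pw) == 45

    def test_empty_table_rejected(self, mag_config, fop_params):
        with pytest.raises(ValueError):
            sequence_loglik(_three_trial_table().iloc[:0], fop_params, "q_fop",
                            mag_config)

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=15, deadline=None)
    def test_choice_probabilities_always_proper(self, seed):
        """First-stage probabilities from random latent states are in (0,1)
        and sum to one."""
        rng = np.random.default_rng(seed)
        state = LatentState()
        state.q_mf_s1 = rng.random(2)
        state.q2 = rng.random((2, 2))
        state.habit = rng.random(2)
        params = ParameterSet(alpha1=0.5, alpha2=0.5, alpha3=0.5, alpha_hop=0.5,
                              beta_mb=float(rng.normal(0, 5)),
                              beta_mf=float(rng.normal(0, 5)),
                              beta_persev=float(rng.normal(0, 5)),
                              beta2=float(rng.normal(0, 5)))
        p = s1_probabilities(state, params, "q_hop")
        assert 0.0 < p[0] < 1.0
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
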