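"""Stay-probability coding, tables, difference scores and regressions."""

import numpy as np
import pandas as pd
import pytest

from twostep.agnostic import (CELLS, code_reward, code_trials, correlate_indices,
                              diff_scores, fit_stay_regression, stay_table)
from twostep.task import TaskConfig, simulate_cohort
from twostep.variants import get_variant


def _table(s1_actions, rewards, transitions=None, subject="s1", valid=None):
    n = len(s1_actions)
    return pd.DataFrame({
        "subject": subject,
        "trial": np.arange(1, n + 1),
        "s1_action": s1_actions,
        "transition": transitions if transitions is not None else ["common"] * n,
        "s2_state": ["B"] * n,
        "s2_action": [0] * n,
        "reward": rewards,
        "rt_ms": np.nan,
        "valid": valid if valid is not None else True,
    })


class TestCodeReward:
    def test_binary_variant_codes_reward_directly(self, prob_config):
        tab = _table([0, 0, 0], [1.0, 0.0, 1.0])
        assert code_reward(tab, prob_config).tolist() == [1, -1, 1]

    def test_magnitude_above_running_mean_is_rewarded(self, mag_config):
        tab = _table([0, 0], [40.0, 60.0])
        # trial 1: 40 < mid-range 50 -> -1; trial 2: 60 > mean(40) -> +1
        assert code_reward(tab, mag_config).tolist() == [-1, 1]

    def test_tie_with_running_mean_codes_unrewarded(self, mag_config):
        tab = _table([0, 0], [50.0, 50.0])
        assert code_reward(tab, mag_config).tolist() == [-1, -1]

    def test_window_limits_history_to_twenty_trials(self, mag_config):
        rewards = [90.0] * 5 + [10.0] * 20 + [15.0]
        tab = _table([0] * 26, rewards)
        codes = code_reward(tab, mag_config)
        # the early 90s have left the 20-trial window: reference is 10 -> +1
        assert codes[-1] == 1

    def test_coding_is_idempotent(self, mag_config):
        tab = _table([0, 1, 0, 1], [30.0, 70.0, 55.0, 20.0])
        a = code_reward(tab, mag_config)
        b = code_reward(tab, mag_config)
        assert np.array_equal(a, b)


class TestStayCoding:
    def test_first_trial_has_no_stay(self, prob_config):
        tab = _table([0, 0, 1], [1.0, 0.0, 1.0])
        coded = code_trials(tab, prob_config)
        assert len(coded) == 2
        assert coded.stay.tolist() == [1, 0]

    def test_predictors_come_from_previous_trial(self, prob_config):
        tab = _table([0, 1], [1.0, 0.0], transitions=["rare", "common"])
        coded = code_trials(tab, prob_config)
        assert coded.iloc[0].rew == 1      # previous trial rewarded
        assert coded.iloc[0].trans == -1   # previous transition rare

    def test_stay_bridges_excluded_trials(self, prob_config):
        valid = [True, False, True]
        tab = _table([0, 1, 0], [1.0, 1.0, 0.0], valid=valid)
        coded = code_trials(tab, prob_config)
        # only valid trials 1 and 3 count; stay compares trial 3 to trial 1
        assert len(coded) == 1
        assert coded.iloc[0].stay == 1


class TestStayTable:
    def test_always_repeat_agent_has_unit_cells(self, prob_config):
        trans = ["common", "rare"] * 10
        tab = _table([0] * 20, [1.0, 0.0] * 10, transitions=trans)
        table = stay_table(code_trials(tab, prob_config))
        assert np.allclose(table.dropna(axis=1).to_numpy(), 1.0)

    def test_uniform_agent_cells_near_half(self):
        cfg = TaskConfig("magnitude", n_trials=10_000)
        means = dict(alpha1=0.0, alpha2=0.0, alpha3=2.0, beta_mb=0.0,
                     beta_mf=0.0, beta_persev=0.0, beta2=0.0)
        data, _ = simulate_cohort(cfg, "q_fop", means,
                                  {p: 0.0 for p in means}, 1, seed=8)
        table = stay_table(code_trials(data, cfg))
        assert np.allclose(table.to_numpy(), 0.5, atol=0.05)

    def test_cell_counts_partition_coded_trials(self, prob_config):
        rng = np.random.default_rng(3)
        tab = _table(rng.integers(0, 2, 200), rng.integers(0, 2, 200).astype(float),
                     transitions=rng.choice(["common", "rare"], 200))
        coded = code_trials(tab, prob_config)
        total = 0
        for name in CELLS:
            t = 1 if name.startswith("common") else -1
            r = 1 if name.endswith("_rewarded") else -1
            total += len(coded[(coded.trans == t) & (coded.rew == r)])
        assert total == len(coded)


class TestDiffScores:
    def test_equal_cells_give_zero_scores(self):
        table = pd.DataFrame([[0.6] * 4], columns=list(CELLS))
        ds = diff_scores(table)
        assert ds.MB_diff.iloc[0] == pytest.approx(0.0)
        assert ds.MF_diff.iloc[0] == pytest.approx(0.0)

    def test_ideal_model_based_pattern(self):
        table = pd.DataFrame([{"common_rewarded": 1.0, "common_unrewarded": 0.0,
                               "rare_rewarded": 0.0, "rare_unrewarded": 1.0}])
        ds = diff_scores(table)
        assert ds.MB_diff.iloc[0] == pytest.approx(2.0)
        assert ds.MF_diff.iloc[0] == pytest.approx(0.0)

    def test_ideal_model_free_pattern(self):
        table = pd.DataFrame([{"common_rewarded": 1.0, "common_unrewarded": 0.0,
                               "rare_rewarded": 1.0, "rare_unrewarded": 0.0}])
        ds = diff_scores(table)
        assert ds.MF_diff.iloc[0] == pytest.approx(2.0)
        assert ds.MB_diff.iloc[0] == pytest.approx(0.0)

    def test_missing_cell_yields_missing_scores(self):
        table = pd.DataFrame([{"common_rewarded": 1.0, "common_unrewarded": np.nan,
                               "rare_rewarded": 0.5, "rare_unrewarded": 0.5}])
        ds = diff_scores(table)
        assert ds.isna().all().all()


def _cohort_coded(means, seed, n_subjects=10, n_trials=250):
    cfg = TaskConfig("magnitude", n_trials=n_trials)
    data, _ = simulate_cohort(cfg, "q_fop", means, {p: 0.1 for p in means},
                              n_subjects, seed)
    return code_trials(data, cfg)


class TestStayRegression:
    def test_pure_mb_cohort_shows_reward_transition_interaction(self):
        coded = _cohort_coded(dict(alpha1=0.0, alpha2=0.9, alpha3=2.0,
                                   beta_mb=10.0, beta_mf=0.0, beta_persev=0.0,
                                   beta2=8.0), seed=21)
        res = fit_stay_regression(coded, n_iter=1000, n_warmup=400, seed=2)
        row = res.coef.loc["rew_x_trans"]
        assert row.estimate > 0
        assert row.ci_low > 0

    def test_pure_mf_cohort_shows_reward_main_effect(self):
        coded = _cohort_coded(dict(alpha1=0.9, alpha2=0.9, alpha3=2.0,
                                   beta_mb=0.0, beta_mf=10.0, beta_persev=0.0,
                                   beta2=8.0), seed=22)
        res = fit_stay_regression(coded, n_iter=1000, n_warmup=400, seed=3)
        row = res.coef.loc["rew"]
        assert row.estimate > 0
        assert row.ci_low > 0

    def test_null_data_slopes_cover_zero(self):
        rng = np.random.default_rng(7)
        covered = {"rew": 0, "trans": 0, "rew_x_trans": 0}
        n_rep = 5
        for rep in range(n_rep):
            coded = pd.DataFrame({
                "subject": np.repeat([f"s{i}" for i in range(8)], 120),
                "stay": rng.integers(0, 2, 8 * 120),
                "rew": rng.choice([-1, 1], 8 * 120),
                "trans": rng.choice([-1, 1], 8 * 120),
            })
            res = fit_stay_regression(coded, n_iter=600, n_warmup=300,
                                      seed=100 + rep)
            for c in covered:
                row = res.coef.loc[c]
                covered[c] += row.ci_low <= 0.0 <= row.ci_high
        for c, k in covered.items():
            assert k >= n_rep - 1, f"{c}: interval covered 0 in {k}/{n_rep}"

    def test_per_subject_mode_matches_signs(self):
        coded = _cohort_coded(dict(alpha1=0.0, alpha2=0.9, alpha3=2.0,
                                   beta_mb=10.0, beta_mf=0.0, beta_persev=0.0,
                                   beta2=8.0), seed=23, n_subjects=6)
        res = fit_stay_regression(coded, mode="per_subject")
        assert (res.subject_coef.b_rew_x_trans > 0).mean() >= 0.8

    def test_hierarchical_needs_two_subjects(self, prob_config):
        tab = _table([0, 1, 0, 1, 0], [1.0, 0.0, 1.0, 0.0, 1.0])
        with pytest.raises(ValueError):
            fit_stay_regression(code_trials(tab, prob_config))


class TestCorrelations:
    def test_identity_and_symmetry(self, rng):
        df = pd.DataFrame(rng.normal(size=(30, 4)), columns=list("abcd"))
        r, p, sig = correlate_indices(df)
        assert np.allclose(np.diag(r), 1.0)
        assert np.allclose(r.to_numpy(), r.to_numpy().T)
        assert sig.loc["a", "a"]

    def test_independent_columns_weakly_correlated(self, rng):
        hits = 0
        for _ in range(20):
            df = pd.DataFrame(rng.normal(size=(100, 2)), columns=["x", "y"])
            r, _, _ = correlate_indices(df)
            hits += abs(r.loc["x", "y"]) < 0.3
        assert hits >= 19

    def test_too_few_subjects_rejected(self, rng):
        df = pd.DataFrame(rng.normal(size=(2, 3)), columns=list("abc"))
        with pytest.raises(ValueError):
            correlate_indices(df)
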