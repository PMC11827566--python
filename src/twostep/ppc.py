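"""Posterior predictive checks and one-step-ahead prediction accuracy.

Generative check: for a thinned subset of retained posterior draws, each
subject's sampled parameters are run through the task simulator on freshly
generated outcome walks, and the four stay-probability cells are summarized
across simulated datasets (mean and 95% HDI).  A well-specified model
should place the empirical stay pattern inside those intervals.

Prediction accuracy: for every valid trial, the first-stage choice
probability is computed conditional on the subject's actual history; the
predicted action is the higher-probability one (ties count half), and the
per-subject proportion of matches is pooled into the min/quartiles/median/
mean/max summary.  Probability-of-observed-choice and simulated-choice
scoring are available as alternatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _core
from .inference import PosteriorFit
from .likelihood import s1_choice_probabilities
from .task import S2_STATES, TaskConfig, generate_outcome_walks
from .variants import PARAM_NAMES, get_variant
from ._core import _NEUTRAL_VEC

CELLS = ("common_rewarded", "common_unrewarded", "rare_rewarded", "rare_unrewarded")


def _pvec_from_named(values: np.ndarray, names: tuple[str, ...]) -> np.ndarray:
    vec = _NEUTRAL_VEC.copy()
    for k, p in enumerate(names):
        vec[PARAM_NAMES.index(p)] = values[k]
    return vec


@dataclass
class PPCSimulations:
    """Simulated datasets from posterior draws, stored as dense arrays.

    All arrays are (n_subjects, n_draws, n_trials); ``reward`` is on the
    task's native scale.  ``to_frame`` materializes one simulated dataset as
    a standard trial table.
    """

    subjects: list
    config: TaskConfig
    s1: np.ndarray
    common: np.ndarray
    s2: np.ndarray
    a2: np.ndarray
    reward: np.ndarray

    @property
    def n_draws(self) -> int:
        return self.s1.shape[1]

    def to_frame(self, subject_index: int, draw: int) -> pd.DataFrame:
        n = self.s1.shape[2]
        return pd.DataFrame({
            "subject": [self.subjects[subject_index]] * n,
            "trial": np.arange(1, n + 1),
            "s1_action": self.s1[subject_index, draw],
            "transition": np.where(self.common[subject_index, draw] == 1,
                                   "common", "rare"),
            "s2_state": np.array(S2_STATES)[self.s2[subject_index, draw]],
            "s2_action": self.a2[subject_index, draw],
            "reward": self.reward[subject_index, draw],
            "rt_ms": np.nan,
            "valid": True,
        })


def posterior_predictive_simulate(fit: PosteriorFit, config: TaskConfig,
                                  n_draws: int = 500,
                                  seed: int | None = None) -> PPCSimulations:
    """Simulate ``n_draws`` full datasets per subject from posterior draws.

    Draws are thinned evenly over the retained chain-major draws; each
    simulation runs on a fresh outcome trajectory from its own child seed.
    """
    if n_draws > fit.n_retained:
        raise ValueError(
            f"n_draws={n_draws} exceeds the {fit.n_retained} retained draws")
    variant = fit.variant
    draws = fit.subject_param_draws()           # (D, S, K) on model scale
    idx = np.linspace(0, draws.shape[0] - 1, n_draws).astype(int)
    S = len(fit.subjects)
    T = config.n_trials

    s1 = np.empty((S, n_draws, T), dtype=np.int64)
    common = np.empty_like(s1)
    s2 = np.empty_like(s1)
    a2 = np.empty_like(s1)
    reward = np.empty((S, n_draws, T))

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(S)
    for s in range(S):
        sim_streams = children[s].spawn(n_draws)
        for d, draw_i in enumerate(idx):
            walk_ss, choice_ss = sim_streams[d].spawn(2)
            outcomes = generate_outcome_walks(config, walk_ss)
            uniforms = np.random.default_rng(choice_ss).random((T, 4))
            pvec = _pvec_from_named(draws[draw_i, s], fit.param_names)
            out = _core.simulate_trials(
                outcomes, config.is_magnitude, uniforms, pvec,
                variant.uses_hop, variant.exploration_code, fit.decay_all,
                config.p_common, config.common0)
            s1[s, d], common[s, d], s2[s, d], a2[s, d], reward[s, d] = out
    return PPCSimulations(subjects=list(fit.subjects), config=config,
                          s1=s1, common=common, s2=s2, a2=a2, reward=reward)


def _stay_cells_dense(s1, common, reward, config: TaskConfig,
                      window: int = 20) -> np.ndarray:
    """Stay-probability cells for dense (..., T) simulation arrays.

    Returns (..., 4) in the order of :data:`CELLS`.  Reward binarization for
    the magnitude variant uses the strict running-mean rule with a mid-range
    first-trial reference (all simulated trials are valid).
    """
    T = s1.shape[-1]
    if config.is_magnitude:
        lo, hi = config.walk_bounds
        csum = np.cumsum(reward, axis=-1)
        t = np.arange(T)
        prev_n = np.minimum(t, window)
        prev_sum = np.where(t[..., :] > 0,
                            csum[..., np.maximum(t - 1, 0)]
                            - np.where(t > window, 1.0, 0.0)
                            * csum[..., np.maximum(t - window - 1, 0)],
                            0.0)
        ref = np.where(prev_n > 0, prev_sum / np.maximum(prev_n, 1), (lo + hi) / 2.0)
        rew = np.where(reward > ref, 1, -1)
    else:
        rew = np.where(reward > 0.5, 1, -1)

    stay = (s1[..., 1:] == s1[..., :-1])
    prev_rew = rew[..., :-1]
    prev_common = common[..., :-1]
    out = np.empty(s1.shape[:-1] + (4,))
    for k, name in enumerate(CELLS):
        mask = (prev_common == (1 if name.startswith("common") else 0)) & \
               (prev_rew == (1 if name.endswith("_rewarded") else -1))
        denom = mask.sum(axis=-1)
        with np.errstate(invalid="ignore"):
            out[..., k] = np.where(denom > 0,
                                   (stay & mask).sum(axis=-1) / np.maximum(denom, 1),
                                   np.nan)
    return out


def ppc_stay_summary(sims: PPCSimulations, hdi_prob: float = 0.95) -> pd.DataFrame:
    """Stay pattern across simulated datasets: per cell, the mean and HDI of
    the subject-averaged stay probability over draws."""
    import arviz as az

    if sims.n_draws < 2:
        raise ValueError("need at least 2 simulated datasets")
    cells = _stay_cells_dense(sims.s1, sims.common, sims.reward, sims.config)
    pooled = np.nanmean(cells, axis=0)          # (D, 4): average over subjects
    rows = []
    for k, name in enumerate(CELLS):
        x = pooled[:, k]
        x = x[~np.isnan(x)]
        if np.ptp(x) == 0.0:
            lo = hi = x[0]
        else:
            lo, hi = az.hdi(x, hdi_prob=hdi_prob)
        rows.append(dict(cell=name, mean=float(x.mean()),
                         hdi_low=float(lo), hdi_high=float(hi)))
    return pd.DataFrame(rows).set_index("cell")


def observed_stay_cells(dataset: pd.DataFrame, config: TaskConfig) -> pd.Series:
    """Subject-averaged empirical stay cells, comparable to the PPC summary."""
    from .agnostic import code_trials, stay_table

    table = stay_table(code_trials(dataset, config))
    return table.mean(axis=0)


def prediction_accuracy(fit: PosteriorFit, dataset: pd.DataFrame,
                        config: TaskConfig, method: str = "argmax",
                        seed: int | None = None):
    """Proportion of correctly predicted first-stage choices per subject.

    ``argmax``: predict the higher-probability action from posterior-mean
    parameters conditional on the observed history (0.5/0.5 ties count
    half).  ``prob``: average probability assigned to the observed choice.
    ``simulate``: sample the predicted choice from the model probability.
    Returns ``(per_subject, summary)``.
    """
    psets = fit.subject_parameter_sets()
    rng = np.random.default_rng(seed)
    acc = {}
    for subject in fit.subjects:
        tab = dataset[dataset.subject == subject]
        if len(tab) == 0:
            raise ValueError(f"subject {subject!r} missing from dataset")
        p0 = s1_choice_probabilities(tab, psets[subject], fit.variant, config,
                                     decay_all=fit.decay_all)
        a1 = tab.sort_values("trial").s1_action.to_numpy()
        valid = tab.sort_values("trial").valid.to_numpy(dtype=bool) \
            if "valid" in tab.columns else np.ones(len(a1), dtype=bool)
        p_obs = np.where(a1 == 0, p0, 1.0 - p0)[valid]
        if method == "argmax":
            score = np.where(p_obs > 0.5, 1.0, np.where(p_obs < 0.5, 0.0, 0.5))
        elif method == "prob":
            score = p_obs
        elif method == "simulate":
            score = (rng.random(len(p_obs)) < p_obs).astype(float)
        else:
            raise ValueError("method must be 'argmax', 'prob' or 'simulate'")
        acc[subject] = float(score.mean())
    per_subject = pd.Series(acc, name="accuracy")
    summary = pd.DataFrame([{
        "min": per_subject.min(),
        "p25": per_subject.quantile(0.25),
        "median": per_subject.median(),
        "mean": per_subject.mean(),
        "p75": per_subject.quantile(0.75),
        "max": per_subject.max(),
    }])
    return per_subject, summary
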