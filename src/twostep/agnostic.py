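"""Model-agnostic stay-probability analyses.

A *stay* is repeating the previous trial's first-stage choice.  Stays are
tabulated and regressed on the previous trial's reward and transition type,
both coded +1/-1 (rewarded/common = +1).  A model-free learner predicts a
main effect of reward on staying; a model-based learner predicts a
reward-by-transition interaction (reward after a rare transition should
*reduce* staying).  For the continuous-magnitude task variant, outcomes are
binarized as rewarded when they exceed the mean outcome over the preceding
20 trials (mid-range reference on the first trial; ties count as
unrewarded).

Difference scores in the Eppinger style condense the four stay cells:

    MF_diff = (P_common,rew + P_rare,rew) - (P_common,unrew + P_rare,unrew)
    MB_diff = (P_common,rew + P_rare,unrew) - (P_common,unrew + P_rare,rew)

The group-level stay regression is a Bayesian hierarchical logistic model
(random intercept and slopes per subject) sharing the package's Gibbs/MH
machinery; the per-subject mode is independent maximum-likelihood logistic
fits used for the correlation analyses.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .inference import _slice_sample_sd, rhat
from .task import TaskConfig

CELLS = ("common_rewarded", "common_unrewarded", "rare_rewarded", "rare_unrewarded")
COEF_NAMES = ("intercept", "rew", "trans", "rew_x_trans")


def code_reward(trials: pd.DataFrame, config: TaskConfig, window: int = 20,
                tie_code: int = -1, first_reference: float | None = None) -> np.ndarray:
    """Per-trial reward coding (+1 rewarded / -1 unrewarded).

    Probability variant: +1 iff the binary reward is 1.  Magnitude variant:
    +1 iff the reward strictly exceeds the mean over the up-to-``window``
    immediately preceding (valid) rewards; the first trial is compared to
    the variant's mid-range.  Rewards exactly equal to the running mean take
    ``tie_code``.
    """
    r = trials.reward.to_numpy(dtype=float)
    if not config.is_magnitude:
        return np.where(r > 0.5, 1, -1)
    if first_reference is None:
        lo, hi = config.walk_bounds
        first_reference = (lo + hi) / 2.0
    valid = trials.valid.to_numpy(dtype=bool) if "valid" in trials.columns \
        else np.ones(len(r), dtype=bool)
    out = np.empty(len(r), dtype=int)
    history: list[float] = []
    for t in range(len(r)):
        ref = float(np.mean(history[-window:])) if history else first_reference
        if r[t] > ref:
            out[t] = 1
        elif r[t] == ref:
            out[t] = tie_code
        else:
            out[t] = -1
        if valid[t]:
            history.append(r[t])
    return out


def code_trials(trials: pd.DataFrame, config: TaskConfig,
                window: int = 20) -> pd.DataFrame:
    """Stay coding for a (possibly multi-subject) trial table.

    Row t (a valid trial with a valid predecessor) carries ``stay`` (current
    first-stage action equals the previous valid trial's) and the previous
    valid trial's reward and transition codes.  First valid trials per
    subject are dropped — no stay is defined there.
    """
    frames = []
    for subject, tab in trials.groupby("subject", sort=False):
        tab = tab.sort_values("trial")
        rew_code = code_reward(tab, config, window=window)
        valid = tab.valid.to_numpy(dtype=bool) if "valid" in tab.columns \
            else np.ones(len(tab), dtype=bool)
        a1 = tab.s1_action.to_numpy()
        trans = np.where(tab.transition.to_numpy() == "common", 1, -1)
        idx = np.flatnonzero(valid)
        if len(idx) < 2:
            continue
        cur, prev = idx[1:], idx[:-1]
        frames.append(pd.DataFrame({
            "subject": subject,
            "trial": tab.trial.to_numpy()[cur],
            "stay": (a1[cur] == a1[prev]).astype(int),
            "rew": rew_code[prev],
            "trans": trans[prev],
        }))
    if not frames:
        raise ValueError("no stay-defined trials in the dataset")
    return pd.concat(frames, ignore_index=True)


def stay_table(coded: pd.DataFrame) -> pd.DataFrame:
    """Per-subject empirical stay probability in each reward x transition cell."""
    rows = {}
    for subject, tab in coded.groupby("subject", sort=False):
        cells = {}
        for name in CELLS:
            trans_v = 1 if name.startswith("common") else -1
            rew_v = 1 if name.endswith("_rewarded") else -1
            sel = tab[(tab.trans == trans_v) & (tab.rew == rew_v)]
            cells[name] = sel.stay.mean() if len(sel) else np.nan
        rows[subject] = cells
    out = pd.DataFrame.from_dict(rows, orient="index")[list(CELLS)]
    out.index.name = "subject"
    return out


def diff_scores(table: pd.DataFrame) -> pd.DataFrame:
    """Eppinger-style MB/MF difference scores from the four stay cells.

    Rows with any missing cell yield missing scores.
    """
    cr, cu = table["common_rewarded"], table["common_unrewarded"]
    rr, ru = table["rare_rewarded"], table["rare_unrewarded"]
    return pd.DataFrame({
        "MF_diff": (cr + rr) - (cu + ru),
        "MB_diff": (cr + ru) - (cu + rr),
    }, index=table.index)


def _design(coded_subject: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    rew = coded_subject.rew.to_numpy(dtype=float)
    trans = coded_subject.trans.to_numpy(dtype=float)
    X = np.column_stack([np.ones_like(rew), rew, trans, rew * trans])
    return X, coded_subject.stay.to_numpy(dtype=float)


@dataclass
class StayRegressionResult:
    """Coefficient table plus diagnostics from the stay regression."""

    mode: str
    coef: pd.DataFrame                     # group coefficients (hierarchical)
    subject_coef: pd.DataFrame | None = None
    rhat: dict = field(default_factory=dict)
    flagged: list = field(default_factory=list)

    @property
    def rhat_max(self) -> float:
        return max(self.rhat.values()) if self.rhat else float("nan")


def _fit_stay_hierarchical(coded: pd.DataFrame, n_chains: int, n_iter: int,
                           n_warmup: int, seed) -> StayRegressionResult:
    subjects = list(pd.unique(coded.subject))
    S = len(subjects)
    designs = [_design(coded[coded.subject == s]) for s in subjects]
    n_max = max(len(y) for _, y in designs)
    X = np.zeros((S, n_max, 4))
    y = np.zeros((S, n_max))
    w = np.zeros((S, n_max))
    for i, (Xi, yi) in enumerate(designs):
        X[i, :len(yi)] = Xi
        y[i, :len(yi)] = yi
        w[i, :len(yi)] = 1.0

    def loglik(eta):
        # Bernoulli-logit, masked over padding
        return np.sum(w * (y * eta - np.logaddexp(0.0, eta)), axis=1)

    ss = np.random.SeedSequence(seed)
    mu_draws = np.empty((n_chains, n_iter - n_warmup, 4))
    sd_draws = np.empty_like(mu_draws)
    b_draws = np.empty((n_chains, n_iter - n_warmup, S, 4))
    tau2 = 10.0 ** 2
    for c, chain_ss in enumerate(ss.spawn(n_chains)):
        rng = np.random.default_rng(chain_ss)
        b = rng.uniform(-0.5, 0.5, size=(S, 4))
        mu = rng.uniform(-0.5, 0.5, size=4)
        sigma = rng.uniform(0.2, 1.0, size=4)
        scales = np.full((S, 4), 0.2)
        acc = np.zeros((S, 4))
        eta = np.einsum("snk,sk->sn", X, b)
        ll = loglik(eta)
        for it in range(n_iter):
            for k in range(4):
                prop = b[:, k] + scales[:, k] * rng.standard_normal(S)
                eta_new = eta + (prop - b[:, k])[:, None] * X[:, :, k]
                ll_new = loglik(eta_new)
                dprior = ((b[:, k] - mu[k]) ** 2 - (prop - mu[k]) ** 2) / (2 * sigma[k] ** 2)
                accept = np.log(rng.random(S)) < (ll_new - ll) + dprior
                b[accept, k] = prop[accept]
                eta[accept] = eta_new[accept]
                ll[accept] = ll_new[accept]
                acc[:, k] += accept
            for k in range(4):
                var = 1.0 / (S / sigma[k] ** 2 + 1.0 / tau2)
                mu[k] = rng.normal(var * b[:, k].sum() / sigma[k] ** 2, np.sqrt(var))
                ssd = float(np.sum((b[:, k] - mu[k]) ** 2))
                sigma[k] = _slice_sample_sd(sigma[k], ssd, S, 10.0, rng)
            if it < n_warmup and (it + 1) % 50 == 0:
                scales *= np.exp(0.5 * (acc / 50 - 0.44))
                np.clip(scales, 1e-3, 2.0, out=scales)
                acc[:] = 0
            if it >= n_warmup:
                j = it - n_warmup
                mu_draws[c, j] = mu
                sd_draws[c, j] = sigma
                b_draws[c, j] = b

    import arviz as az

    rows = []
    diags = {}
    for k, name in enumerate(COEF_NAMES):
        draws = mu_draws[:, :, k]
        lo, hi = az.hdi(draws.reshape(-1), hdi_prob=0.95)
        diags[f"mu_{name}"] = rhat(draws)
        diags[f"sigma_{name}"] = rhat(sd_draws[:, :, k])
        rows.append(dict(coef=name, estimate=float(draws.mean()),
                         ci_low=float(lo), ci_high=float(hi),
                         sd=float(draws.std(ddof=1))))
    subj = pd.DataFrame(b_draws.reshape(-1, S, 4).mean(axis=0),
                        columns=[f"b_{n}" for n in COEF_NAMES],
                        index=pd.Index(subjects, name="subject"))
    return StayRegressionResult(mode="hierarchical",
                                coef=pd.DataFrame(rows).set_index("coef"),
                                subject_coef=subj, rhat=diags)


def _logistic_nll(b, X, y, ridge):
    eta = X @ b
    return -(np.sum(y * eta - np.logaddexp(0.0, eta))) + ridge * np.sum(b ** 2)


def _fit_stay_per_subject(coded: pd.DataFrame, clip: float = 10.0) -> StayRegressionResult:
    rows = []
    flagged = []
    for subject, tab in coded.groupby("subject", sort=False):
        X, y = _design(tab)
        res = minimize(_logistic_nll, np.zeros(4), args=(X, y, 0.0), method="BFGS")
        b = res.x
        if not res.success or np.any(np.abs(b) > clip):
            # quasi-separation: refit with a light ridge penalty and flag
            res = minimize(_logistic_nll, np.zeros(4), args=(X, y, 0.5), method="BFGS")
            b = np.clip(res.x, -clip, clip)
            flagged.append(subject)
        rows.append(dict(subject=subject,
                         **{f"b_{n}": b[k] for k, n in enumerate(COEF_NAMES)}))
    subj = pd.DataFrame(rows).set_index("subject")
    group = pd.DataFrame({
        "estimate": subj.mean(),
        "ci_low": subj.mean() - 1.96 * subj.sem(),
        "ci_high": subj.mean() + 1.96 * subj.sem(),
        "sd": subj.std(ddof=1),
    })
    group.index = [n.removeprefix("b_") for n in group.index]
    group.index.name = "coef"
    return StayRegressionResult(mode="per_subject", coef=group,
                                subject_coef=subj, flagged=flagged)


def fit_stay_regression(coded: pd.DataFrame, mode: str = "hierarchical",
                        n_chains: int = 4, n_iter: int = 1500,
                        n_warmup: int = 500, seed=None) -> StayRegressionResult:
    """Logistic regression of staying on previous reward, transition and
    their interaction.

    ``hierarchical`` fits group-level coefficients with subject-level random
    intercept and slopes (posterior means and 95% HDIs); ``per_subject``
    fits each subject independently by maximum likelihood (separation is
    ridge-regularized and flagged).
    """
    if mode == "hierarchical":
        if coded.subject.nunique() < 2:
            raise ValueError("hierarchical mode needs at least 2 subjects")
        return _fit_stay_hierarchical(coded, n_chains, n_iter, n_warmup, seed)
    if mode == "per_subject":
        return _fit_stay_per_subject(coded)
    raise ValueError("mode must be 'hierarchical' or 'per_subject'")


def correlate_indices(indices: pd.DataFrame, method: str = "pearson",
                      alpha: float = 0.05):
    """Pairwise correlations across per-subject indices with significance flags.

    ``indices`` has one row per subject and one column per index (regression
    weights, difference scores, model parameters, mean reward, ...).
    Returns ``(r, p, significant)`` DataFrames; non-significant cells in
    ``significant`` are False, mirroring blank tiles in a correlation plot.
    """
    from scipy import stats

    if len(indices) < 3:
        raise ValueError("correlation analyses need at least 3 subjects")
    cols = list(indices.columns)
    k = len(cols)
    r = np.eye(k)
    p = np.zeros((k, k))
    fun = stats.pearsonr if method == "pearson" else stats.spearmanr
    for i in range(k):
        for j in range(i + 1, k):
            pair = indices[[cols[i], cols[j]]].dropna()
            rij, pij = fun(pair.iloc[:, 0], pair.iloc[:, 1])
            r[i, j] = r[j, i] = rij
            p[i, j] = p[j, i] = pij
    r_df = pd.DataFrame(r, index=cols, columns=cols)
    p_df = pd.DataFrame(p, index=cols, columns=cols)
    sig = (p_df < alpha)
    np.fill_diagonal(sig.values, True)
    return r_df, p_df, sig
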