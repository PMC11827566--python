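"""Model comparison via PSIS-LOO and WAIC.

Predictive accuracy is scored by the expected log pointwise predictive
density (elpd) estimated with Pareto-smoothed importance-sampling
leave-one-out cross-validation; the pointwise unit is one trial (first- and
second-stage log terms summed).  Models are ranked by elpd, differences to
the best model are computed from paired pointwise contributions, and the
evidence ratio |elpd_diff| / se_diff summarizes how reliable the advantage
is.  When the difference overlaps zero within one standard error, the more
parsimonious model (fewer free parameters) is preferred.

PSIS-LOO is delegated to arviz (generalized-Pareto smoothing of the top 20%
of importance weights, Pareto-k > 0.7 flagged); WAIC is computed directly
from the draws-by-points matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .inference import PosteriorFit

PARETO_K_WARN = 0.7


def _to_idata(pointwise: np.ndarray, n_chains: int):
    import arviz as az

    d, n = pointwise.shape
    if d % n_chains:
        raise ValueError("draw count not divisible by n_chains")
    # arviz requires a posterior group to be present, even though loo only
    # reads the log_likelihood group
    return az.from_dict(
        posterior={"_placeholder": np.zeros((n_chains, d // n_chains))},
        log_likelihood={"obs": pointwise.reshape(n_chains, d // n_chains, n)})


@dataclass
class LooResult:
    elpd: float
    se: float
    p_loo: float
    pointwise: np.ndarray  # per-point elpd contributions
    pareto_k: np.ndarray

    @property
    def n_bad_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_WARN))


def psis_loo(pointwise_loglik: np.ndarray, n_chains: int = 1) -> LooResult:
    """PSIS-LOO elpd with standard error and per-point Pareto-k diagnostics.

    ``pointwise_loglik`` is (draws, points).  Degenerate (all-identical)
    draws make importance weights meaningless; they are flagged through the
    Pareto-k values arviz reports.
    """
    import arviz as az

    pointwise_loglik = np.asarray(pointwise_loglik, dtype=float)
    if not np.isfinite(pointwise_loglik).all():
        raise ValueError("pointwise log-likelihoods must be finite")
    res = az.loo(_to_idata(pointwise_loglik, n_chains), pointwise=True)
    return LooResult(elpd=float(res.elpd_loo), se=float(res.se),
                     p_loo=float(res.p_loo),
                     pointwise=np.asarray(res.loo_i.values, dtype=float),
                     pareto_k=np.asarray(res.pareto_k.values, dtype=float))


def waic(pointwise_loglik: np.ndarray) -> float:
    """Widely applicable information criterion, -2 * (lppd - p_waic),
    with the variance-based effective-parameter count."""
    ll = np.asarray(pointwise_loglik, dtype=float)
    d = ll.shape[0]
    lppd = logsumexp(ll, axis=0) - np.log(d)
    p = ll.var(axis=0, ddof=1) if d > 1 else np.zeros(ll.shape[1])
    return float(-2.0 * (lppd.sum() - p.sum()))


def p_waic(pointwise_loglik: np.ndarray) -> float:
    ll = np.asarray(pointwise_loglik, dtype=float)
    return float(ll.var(axis=0, ddof=1).sum()) if ll.shape[0] > 1 else 0.0


def evidence_ratio(elpd_diff: float, se_diff: float) -> float:
    """|elpd_diff| / se_diff — the benefit in predictive density relative to
    its uncertainty; conventional reading: ~>2 moderate, <2 weak."""
    if se_diff == 0:
        return float("nan")
    return abs(elpd_diff) / se_diff


def compare(fits, n_chains: int | None = None) -> pd.DataFrame:
    """Rank models by PSIS-LOO elpd and score differences to the best.

    ``fits`` is either a mapping of model name -> (draws, points) pointwise
    log-likelihood matrix, or a list of :class:`PosteriorFit` objects (same
    dataset, same pointwise partition).  Differences use paired pointwise
    elpd contributions, so ``se_diff = sqrt(n * var(pointwise diffs))``.

    Returns a table (one row per model, best first) with columns ``elpd``,
    ``elpd_se``, ``elpd_diff`` (magnitude of the deficit vs. the best model,
    0 for the best), ``se_diff``, ``evidence_ratio``, ``waic`` and
    ``n_params``; the parsimony-aware choice is stored in
    ``result.attrs["preferred"]``.
    """
    if isinstance(fits, dict):
        items = list(fits.items())
        n_params = {k: np.nan for k, _ in items}
        chains = {k: (n_chains or 1) for k, _ in items}
    else:
        items = []
        n_params = {}
        chains = {}
        for f in fits:
            if not isinstance(f, PosteriorFit):
                raise TypeError("compare expects PosteriorFit objects or a dict")
            items.append((f.variant.name, f.pointwise))
            n_params[f.variant.name] = len(f.param_names)
            chains[f.variant.name] = f.sampler.n_chains if f.sampler else (n_chains or 1)

    n_points = {k: m.shape[1] for k, m in items}
    if len(set(n_points.values())) > 1:
        raise ValueError(f"pointwise partitions differ across models: {n_points}")

    loos = {k: psis_loo(m, chains[k]) for k, m in items}
    waics = {k: waic(m) for k, m in items}
    best = max(loos, key=lambda k: loos[k].elpd)

    rows = []
    for k, _ in items:
        if k == best:
            diff, se_d = 0.0, 0.0
        else:
            d_i = loos[best].pointwise - loos[k].pointwise
            diff = float(d_i.sum())
            se_d = float(np.sqrt(len(d_i) * d_i.var(ddof=1)))
        rows.append(dict(model=k, elpd=loos[k].elpd, elpd_se=loos[k].se,
                         elpd_diff=diff, se_diff=se_d,
                         evidence_ratio=evidence_ratio(diff, se_d),
                         waic=waics[k], n_params=n_params[k],
                         n_bad_pareto_k=loos[k].n_bad_k))
    table = pd.DataFrame(rows).sort_values("elpd", ascending=False,
                                           ignore_index=True)

    # parsimony rule: among models overlapping the best within one se_diff,
    # prefer the one with the fewest free parameters
    contenders = table[(table.elpd_diff <= table.se_diff)]
    if contenders.n_params.notna().all() and len(contenders) > 1:
        preferred = contenders.sort_values(["n_params", "elpd_diff"]).iloc[0].model
    else:
        preferred = best
    table.attrs["preferred"] = preferred
    table.attrs["best"] = best
    return table
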