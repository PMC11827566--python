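"""Model/Results front end, statsmodels-style.

:class:`HybridTwoStepModel` binds a trial dataset to one model variant and a
task configuration; ``fit()`` runs hierarchical Bayesian estimation (or the
deterministic point-estimate mode) and returns a
:class:`HybridTwoStepResults` carrying draws, diagnostics, ``summary()``,
predictive scores and posterior predictive simulation.

Example
-------
>>> from twostep import HybridTwoStepModel, TaskConfig, SamplerConfig
>>> from twostep.task import simulate_cohort
>>> cfg = TaskConfig("magnitude")
>>> data, truth = simulate_cohort(cfg, "q_hop",
...     {"alpha1": 0., "alpha2": 0.5, "alpha3": 1., "alpha_hop": 0.,
...      "beta_mb": 5., "beta_mf": 1., "beta_persev": 1.5, "beta2": 5.},
...     {k: 0.3 for k in ("alpha1", "alpha2", "alpha3", "alpha_hop",
...                       "beta_mb", "beta_mf", "beta_persev", "beta2")},
...     n_subjects=10, seed=7)
>>> res = HybridTwoStepModel(data, "q_hop", cfg).fit(
...     sampler=SamplerConfig.test_scale(seed=1))
>>> res.rhat_max <= 1.1  # doctest: +SKIP
True
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import comparison as _comparison
from . import ppc as _ppc
from .inference import (MapFit, PosteriorFit, PriorSpec, SamplerConfig,
                        fit_hierarchical, fit_map)
from .io import filter_trials, read_trial_table
from .likelihood import sequence_loglik
from .task import TaskConfig
from .variants import ModelVariant, ParameterSet, get_variant


class HybridTwoStepModel:
    """A hybrid RL model variant bound to a multi-subject trial dataset."""

    def __init__(self, data: pd.DataFrame, variant: ModelVariant | str = "q_hop",
                 task: TaskConfig | None = None, rt_threshold_ms: float = 150.0,
                 decay_all: bool = False):
        self.variant = get_variant(variant)
        self.task = task or TaskConfig()
        self.decay_all = decay_all
        data, self.filter_report = filter_trials(data, rt_threshold_ms)
        self.data = data

    @classmethod
    def from_csv(cls, path, variant="q_hop", task: TaskConfig | None = None,
                 **kw) -> "HybridTwoStepModel":
        task = task or TaskConfig()
        return cls(read_trial_table(path, task), variant, task, **kw)

    @property
    def subjects(self) -> list:
        return list(pd.unique(self.data.subject))

    def loglik(self, params: ParameterSet | dict, subject=None) -> float:
        """Total sequence log-likelihood at fixed parameters (one subject, or
        summed over all subjects when ``subject`` is None)."""
        subjects = [subject] if subject is not None else self.subjects
        total = 0.0
        for s in subjects:
            t, _ = sequence_loglik(self.data[self.data.subject == s], params,
                                   self.variant, self.task,
                                   decay_all=self.decay_all)
            total += t
        return total

    def fit(self, method: str = "mcmc", sampler: SamplerConfig | None = None,
            priors: PriorSpec | None = None, **kw) -> "HybridTwoStepResults":
        if method == "mcmc":
            fit = fit_hierarchical(self.data, self.variant, self.task,
                                   priors=priors, sampler=sampler,
                                   decay_all=self.decay_all)
        elif method == "map":
            fit = fit_map(self.data, self.variant, self.task, priors=priors,
                          decay_all=self.decay_all, **kw)
        else:
            raise ValueError("method must be 'mcmc' or 'map'")
        return HybridTwoStepResults(self, fit)


class HybridTwoStepResults:
    """Estimates, uncertainties and predictive diagnostics of one fit."""

    def __init__(self, model: HybridTwoStepModel, fit: PosteriorFit | MapFit):
        self.model = model
        self.fit = fit

    # -- estimates -----------------------------------------------------
    @property
    def is_mcmc(self) -> bool:
        return isinstance(self.fit, PosteriorFit)

    @property
    def params(self) -> pd.DataFrame:
        """Subject-level point estimates on the model scale."""
        if self.is_mcmc:
            return self.fit.subject_posterior_mean()
        return self.fit.subject_params()

    @property
    def rhat_max(self) -> float:
        return self.fit.rhat_max if self.is_mcmc else float("nan")

    @property
    def converged(self) -> bool:
        return self.fit.converged

    def summary(self) -> str:
        lines = [
            f"Hybrid two-step model: {self.model.variant.name}",
            f"subjects: {len(self.model.subjects)}, "
            f"trials: {len(self.model.data)} "
            f"({int(self.model.data.valid.sum())} valid)",
        ]
        if self.is_mcmc:
            s = self.fit.sampler
            lines += [
                f"MCMC: {s.n_chains} chains x {s.n_iter} iterations "
                f"({s.n_warmup} warm-up), {self.fit.n_retained} retained draws",
                f"max split R-hat: {self.rhat_max:.3f} "
                f"({'converged' if self.converged else 'NOT converged'})",
                "",
                "Group-level posterior (rates on (0,1) scale):",
                self.fit.group_summary().round(3).to_string(index=False),
            ]
        else:
            lines += [
                "Penalized MAP point estimates",
                f"log-posterior: {self.fit.log_posterior:.2f}",
                "",
                "Group means (raw scale):",
                pd.Series(self.fit.group_mean,
                          index=list(self.fit.param_names)).round(3).to_string(),
            ]
        return "\n".join(lines)

    # -- predictive scores ---------------------------------------------
    def loo(self) -> _comparison.LooResult:
        self._require_mcmc()
        return _comparison.psis_loo(self.fit.pointwise,
                                    self.fit.sampler.n_chains)

    def waic(self) -> float:
        self._require_mcmc()
        return _comparison.waic(self.fit.pointwise)

    # -- posterior predictive ------------------------------------------
    def simulate(self, n_draws: int = 500, seed=None) -> _ppc.PPCSimulations:
        self._require_mcmc()
        return _ppc.posterior_predictive_simulate(self.fit, self.model.task,
                                                  n_draws=n_draws, seed=seed)

    def ppc_stay_summary(self, n_draws: int = 500, seed=None) -> pd.DataFrame:
        return _ppc.ppc_stay_summary(self.simulate(n_draws, seed))

    def prediction_accuracy(self, method: str = "argmax", seed=None):
        self._require_mcmc()
        return _ppc.prediction_accuracy(self.fit, self.model.data,
                                        self.model.task, method=method,
                                        seed=seed)

    def save(self, path) -> None:
        self._require_mcmc()
        self.fit.save(path)

    def _require_mcmc(self) -> None:
        if not self.is_mcmc:
            raise ValueError("this operation needs an MCMC fit "
                             "(fit(method='mcmc'))")


def compare_results(results: list[HybridTwoStepResults]) -> pd.DataFrame:
    """Rank fitted models by PSIS-LOO elpd (see :func:`twostep.comparison.compare`)."""
    return _comparison.compare([r.fit for r in results])
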