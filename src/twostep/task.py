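"""Two-step-task environments and synthetic agents.

Two task variants are supported:

* ``magnitude`` — modified task: each of the four second-stage options pays a
  continuous reward magnitude drifting between 0 and 100 (rounded to the
  nearest integer) under a reflecting Gaussian random walk; 300 trials by
  default.
* ``probability`` — classic task: each option pays a binary reward with a
  probability drifting in [0.25, 0.75]; 200 trials by default.

First-stage actions lead to one of two second-stage states through a fixed
70/30 transition structure.  Agents are simulated forward from any model
variant with known parameters, which makes every downstream stage (fitting,
comparison, predictive checks) testable without empirical data.

Seed discipline: each public entry point takes one seed and derives
independent child streams (outcome walks, choice/transition/reward draws,
subject-level parameter draws) via :class:`numpy.random.SeedSequence`, so
identical inputs reproduce outputs bit-exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import numpy as np
import pandas as pd

from . import _core
from .variants import ModelVariant, ParameterSet, RATE_PARAMS, get_variant, transform_rate

S2_STATES = ("B", "C")

#: Default group-level moments (raw scale) for synthetic cohorts.  Means are
#: anchored to typical group estimates for the magnitude-variant task under
#: the winning higher-order-perseveration model (rates via the inverse
#: normal CDF: alpha1 ~ .38, alpha2 ~ .82, alpha3 ~ .99, alpha_hop ~ .57);
#: SDs are moderate between-subject spreads (0.4 raw for rates, roughly a
#: quarter of the mean for the SoftMax weights) keeping every simulated
#: subject's parameters in an identifiable regime.
DEFAULT_GROUP_MEANS = {
    "alpha1": -0.305, "alpha2": 0.915, "alpha3": 2.326, "alpha_hop": 0.176,
    "beta_mb": 10.59, "beta_mf": 1.39, "beta_persev": 1.44, "beta2": 9.76,
    "phi": 0.25,
}
DEFAULT_GROUP_SDS = {
    "alpha1": 0.4, "alpha2": 0.4, "alpha3": 0.4, "alpha_hop": 0.4,
    "beta_mb": 3.5, "beta_mf": 0.5, "beta_persev": 0.5, "beta2": 2.4,
    "phi": 0.15,
}

_DEFAULTS = {
    "magnitude": dict(n_trials=300, walk_step_sd=2.5, walk_bounds=(0.0, 100.0)),
    "probability": dict(n_trials=200, walk_step_sd=0.025, walk_bounds=(0.25, 0.75)),
}


@dataclass(frozen=True)
class TaskConfig:
    """Environment settings for one task variant.

    Leaving ``n_trials``, ``walk_step_sd`` or ``walk_bounds`` unset picks the
    variant's convention (magnitude: 300 trials, step SD 2.5, bounds [0, 100];
    probability: 200 trials, step SD 0.025, bounds [0.25, 0.75]).
    ``common_state_action0`` names the second-stage state that first-stage
    action 0 reaches on a common transition; action 1's common destination is
    the other state.
    """

    variant: str = "magnitude"
    n_trials: int | None = None
    p_common: float = 0.7
    walk_step_sd: float | None = None
    walk_bounds: tuple[float, float] | None = None
    common_state_action0: str = "B"
    seed: int | None = None

    def __post_init__(self):
        if self.variant not in _DEFAULTS:
            raise ValueError(f"unknown task variant {self.variant!r}")
        d = _DEFAULTS[self.variant]
        if self.n_trials is None:
            object.__setattr__(self, "n_trials", d["n_trials"])
        if self.walk_step_sd is None:
            object.__setattr__(self, "walk_step_sd", d["walk_step_sd"])
        if self.walk_bounds is None:
            object.__setattr__(self, "walk_bounds", d["walk_bounds"])
        if not (0.5 < self.p_common <= 1.0):
            raise ValueError("p_common must lie in (0.5, 1]")
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.walk_step_sd < 0:
            raise ValueError("walk_step_sd must be non-negative")
        lo, hi = self.walk_bounds
        if not lo < hi:
            raise ValueError("walk_bounds lower bound must be below the upper")
        if self.common_state_action0 not in S2_STATES:
            raise ValueError("common_state_action0 must be 'B' or 'C'")

    @property
    def is_magnitude(self) -> bool:
        return self.variant == "magnitude"

    @property
    def common0(self) -> int:
        """Integer index of action 0's common destination (B=0, C=1)."""
        return S2_STATES.index(self.common_state_action0)

    def common_state(self, s1_action: int) -> int:
        return self.common0 if s1_action == 0 else 1 - self.common0

    def with_trials(self, n_trials: int) -> "TaskConfig":
        return replace(self, n_trials=n_trials)


def generate_outcome_walks(config: TaskConfig, seed: int | None = None) -> np.ndarray:
    """Four independent reflecting Gaussian random walks, one per S2 option.

    Returns an ``(n_trials, 4)`` array (option order B0, B1, C0, C1).
    Magnitude-variant values are rounded to the nearest integer.  Reflection
    is implemented by folding the free walk at the boundaries, which is
    path-wise identical to reflecting each step.
    """
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)
    lo, hi = config.walk_bounds
    width = hi - lo
    x0 = rng.uniform(lo, hi, size=4)
    steps = rng.normal(0.0, config.walk_step_sd, size=(config.n_trials, 4)) \
        if config.walk_step_sd > 0 else np.zeros((config.n_trials, 4))
    steps[0] = 0.0
    free = x0 + np.cumsum(steps, axis=0)
    z = np.mod(free - lo, 2.0 * width)
    walks = lo + np.where(z <= width, z, 2.0 * width - z)
    if config.is_magnitude:
        walks = np.rint(walks)
    return walks


def sample_transition(s1_action: int, config: TaskConfig,
                      rng: np.random.Generator | int | None = None):
    """Draw (transition label, S2 state label) for one first-stage action."""
    if s1_action not in (0, 1):
        raise ValueError("s1_action must be 0 or 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    common = rng.random() < config.p_common
    state = config.common_state(s1_action) if common else 1 - config.common_state(s1_action)
    return ("common" if common else "rare"), S2_STATES[state]


def _assemble_table(subject, s1, common, s2, a2, reward) -> pd.DataFrame:
    n = len(s1)
    return pd.DataFrame(
        {
            "subject": [subject] * n,
            "trial": np.arange(1, n + 1),
            "s1_action": s1.astype(int),
            "transition": np.where(common == 1, "common", "rare"),
            "s2_state": np.array(S2_STATES)[s2],
            "s2_action": a2.astype(int),
            "reward": reward,
            "rt_ms": np.full(n, np.nan),
            "valid": np.ones(n, dtype=bool),
        }
    )


def simulate_agent(config: TaskConfig, variant: ModelVariant | str,
                   params: ParameterSet | Mapping, seed: int,
                   subject: str = "sim", outcomes: np.ndarray | None = None) -> pd.DataFrame:
    """Simulate one agent's full trial table under known parameters.

    The agent chooses by the variant's SoftMax rule given its evolving latent
    state; transitions, binary rewards and choices are all driven by child
    streams of ``seed``.  Pass ``outcomes`` to reuse a fixed outcome
    trajectory instead of generating fresh walks.
    """
    variant = get_variant(variant)
    if isinstance(params, Mapping):
        params = ParameterSet.from_dict(dict(params))
    pvec = params.as_vector(variant)

    ss = np.random.SeedSequence(seed)
    walk_ss, choice_ss = ss.spawn(2)
    if outcomes is None:
        outcomes = generate_outcome_walks(config, walk_ss)
    elif outcomes.shape != (config.n_trials, 4):
        raise ValueError("outcomes must have shape (n_trials, 4)")
    uniforms = np.random.default_rng(choice_ss).random((config.n_trials, 4))

    s1, common, s2, a2, reward = _core.simulate_trials(
        np.asarray(outcomes, dtype=float), config.is_magnitude, uniforms,
        pvec, variant.uses_hop, variant.exploration_code, False,
        config.p_common, config.common0)
    return _assemble_table(subject, s1, common, s2, a2, reward)


def draw_subject_parameters(variant: ModelVariant | str,
                            group_means: Mapping[str, float],
                            group_sds: Mapping[str, float],
                            n_subjects: int,
                            rng: np.random.Generator,
                            truncate: float | None = 2.5) -> tuple[np.ndarray, pd.DataFrame]:
    """Draw subject-level raw parameters from group-level Gaussians.

    Means and SDs are on the raw (unconstrained) scale; rate-type parameters
    are mapped through the standard-normal CDF, mirroring the transform used
    during inference.  Subject deviations are drawn from a symmetric
    truncated Gaussian (``truncate`` SDs, default 2.5; ``None`` disables)
    so that a simulated cohort contains no pathological outlier subjects —
    the usual convention in parameter-recovery studies.  Returns the raw
    draws (n_subjects, K) and a tidy truth table with both scales.
    """
    variant = get_variant(variant)
    free = variant.free_params
    missing = [p for p in free if p not in group_means or p not in group_sds]
    if missing:
        raise ValueError(f"missing group moments for parameters {missing}")
    sds = np.array([group_sds[p] for p in free], dtype=float)
    if np.any(sds < 0):
        raise ValueError("group SDs must be non-negative")
    means = np.array([group_means[p] for p in free], dtype=float)
    if truncate is None:
        z = rng.standard_normal((n_subjects, len(free)))
    else:
        from scipy.stats import truncnorm
        z = truncnorm.ppf(rng.random((n_subjects, len(free))),
                          -truncate, truncate)
    raw = means + sds * z

    rows = []
    for s in range(n_subjects):
        sid = f"s{s + 1:03d}"
        for k, p in enumerate(free):
            value = transform_rate(raw[s, k]) if p in RATE_PARAMS else raw[s, k]
            rows.append((sid, p, raw[s, k], value))
    truth = pd.DataFrame(rows, columns=["subject", "parameter", "raw", "value"])
    return raw, truth


def simulate_cohort(config: TaskConfig, variant: ModelVariant | str,
                    group_means: Mapping[str, float],
                    group_sds: Mapping[str, float],
                    n_subjects: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a multi-subject dataset plus its ground-truth parameters.

    Returns ``(dataset, truth)``: a long trial table over all subjects and a
    tidy per-subject parameter table (columns subject, parameter, raw,
    value), the latter suitable for recovery checks against a fit.
    """
    if n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    variant = get_variant(variant)
    ss = np.random.SeedSequence(seed)
    param_ss, *subject_ss = ss.spawn(1 + n_subjects)
    raw, truth = draw_subject_parameters(
        variant, group_means, group_sds, n_subjects,
        np.random.default_rng(param_ss))

    tables = []
    for s in range(n_subjects):  # one independent child stream per subject
        sid = f"s{s + 1:03d}"
        pset = ParameterSet.from_dict(
            dict(zip(truth.loc[truth.subject == sid, "parameter"],
                     truth.loc[truth.subject == sid, "value"])))
        child_seed = int(subject_ss[s].generate_state(1)[0] % (2 ** 31))
        tables.append(simulate_agent(config, variant, pset, child_seed, subject=sid))
    return pd.concat(tables, ignore_index=True), truth


def default_cohort(config: TaskConfig, variant: ModelVariant | str,
                   n_subjects: int, seed: int) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate a cohort under the package's canonical group-level moments
    (:data:`DEFAULT_GROUP_MEANS` / :data:`DEFAULT_GROUP_SDS`), restricted to
    the variant's free parameters."""
    variant = get_variant(variant)
    means = {p: DEFAULT_GROUP_MEANS[p] for p in variant.free_params}
    sds = {p: DEFAULT_GROUP_SDS[p] for p in variant.free_params}
    return simulate_cohort(config, variant, means, sds, n_subjects, seed)
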