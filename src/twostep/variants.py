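"""Model variants and parameter sets for the hybrid two-step-task models.

Six variants span the cross of perseveration scheme (first-order FOP vs.
higher-order HOP) and directed-exploration bonus (none, bandit-counter,
trial-counter):

====================  =========  ============
name                  uses_hop   exploration
====================  =========  ============
``q_fop``             False      none
``q_bandit``          False      bandit
``q_trial``           False      trial
``q_hop``             True       none
``q_bandit_hop``      True       bandit
``q_trial_hop``       True       trial
====================  =========  ============

All variants share the SARSA/forgetting Q-learner; the free-parameter set is
the seven base parameters plus ``alpha_hop`` iff the variant uses the
habitual controller and ``phi`` iff it carries an exploration bonus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Iterable

import numpy as np
from scipy.stats import norm

#: canonical ordering of the full parameter vector used by the kernels
PARAM_NAMES = (
    "alpha1",
    "alpha2",
    "alpha3",
    "alpha_hop",
    "beta_mb",
    "beta_mf",
    "beta_persev",
    "beta2",
    "phi",
)

#: learning/decay/step-size parameters constrained to (0, 1)
RATE_PARAMS = frozenset({"alpha1", "alpha2", "alpha3", "alpha_hop"})

_EXPLORATION_CODES = {"none": 0, "bandit": 1, "trial": 2}


@dataclass(frozen=True)
class ModelVariant:
    """One member of the model space.

    Parameters
    ----------
    name : str
        Registry key, e.g. ``"q_trial_hop"``.
    uses_hop : bool
        Whether first-stage perseveration is the habit vector H_t
        (higher-order) rather than the previous-choice indicator.
    exploration : {"none", "bandit", "trial"}
        Directed-exploration heuristic feeding the first-stage bonus.
    """

    name: str
    uses_hop: bool
    exploration: str

    def __post_init__(self) -> None:
        if self.exploration not in _EXPLORATION_CODES:
            raise ValueError(f"unknown exploration heuristic {self.exploration!r}")

    @property
    def exploration_code(self) -> int:
        return _EXPLORATION_CODES[self.exploration]

    @property
    def free_params(self) -> tuple[str, ...]:
        """Free parameters of this variant, in canonical order."""
        names = []
        for p in PARAM_NAMES:
            if p == "alpha_hop" and not self.uses_hop:
                continue
            if p == "phi" and self.exploration == "none":
                continue
            names.append(p)
        return tuple(names)

    @property
    def free_index(self) -> np.ndarray:
        """Indices of the free parameters within the full 9-vector."""
        return np.array([PARAM_NAMES.index(p) for p in self.free_params], dtype=np.int64)


VARIANTS: dict[str, ModelVariant] = {
    v.name: v
    for v in (
        ModelVariant("q_fop", False, "none"),
        ModelVariant("q_bandit", False, "bandit"),
        ModelVariant("q_trial", False, "trial"),
        ModelVariant("q_hop", True, "none"),
        ModelVariant("q_bandit_hop", True, "bandit"),
        ModelVariant("q_trial_hop", True, "trial"),
    )
}


def get_variant(name: str | ModelVariant) -> ModelVariant:
    if isinstance(name, ModelVariant):
        return name
    try:
        return VARIANTS[name.lower()]
    except KeyError:
        raise KeyError(
            f"unknown model variant {name!r}; choose from {sorted(VARIANTS)}"
        ) from None


# neutral values used for parameters a variant does not carry (they are
# guarded by the kernel flags, so the values never enter the likelihood)
_NEUTRAL = {
    "alpha1": 0.5,
    "alpha2": 0.5,
    "alpha3": 1.0,
    "alpha_hop": 1.0,
    "beta_mb": 0.0,
    "beta_mf": 0.0,
    "beta_persev": 0.0,
    "beta2": 0.0,
    "phi": 0.0,
}


@dataclass
class ParameterSet:
    """Subject-level parameters on the model (transformed) scale.

    Rates live strictly inside (0, 1); inverse temperatures and the
    exploration weight are unconstrained reals.  Parameters that a variant
    does not use may be left as ``None``.
    """

    alpha1: float | None = None
    alpha2: float | None = None
    alpha3: float | None = None
    alpha_hop: float | None = None
    beta_mb: float | None = None
    beta_mf: float | None = None
    beta_persev: float | None = None
    beta2: float | None = None
    phi: float | None = None

    def validate(self, variant: ModelVariant) -> None:
        """Raise if the set does not match the variant's free parameters."""
        free = set(variant.free_params)
        for f in fields(self):
            val = getattr(self, f.name)
            if f.name in free:
                if val is None:
                    raise ValueError(f"{variant.name} requires parameter {f.name!r}")
                if f.name in RATE_PARAMS and not (0.0 < val < 1.0):
                    raise ValueError(f"{f.name}={val} outside the open interval (0, 1)")
            elif val is not None:
                raise ValueError(
                    f"parameter {f.name!r} supplied but {variant.name} does not use it"
                )

    def as_vector(self, variant: ModelVariant) -> np.ndarray:
        """Pack into the full 9-vector, filling unused slots with neutral values."""
        self.validate(variant)
        vec = np.empty(len(PARAM_NAMES))
        for i, p in enumerate(PARAM_NAMES):
            val = getattr(self, p)
            vec[i] = _NEUTRAL[p] if val is None else float(val)
        return vec

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSet":
        return cls(**{k: v for k, v in d.items() if k in PARAM_NAMES})

    def to_dict(self, variant: ModelVariant | None = None) -> dict:
        names: Iterable[str] = variant.free_params if variant else PARAM_NAMES
        return {p: getattr(self, p) for p in names if getattr(self, p) is not None}


_RATE_EPS = 1e-12


def transform_rate(raw):
    """Map an unconstrained raw parameter to (0, 1) via the standard-normal CDF.

    The output is clipped a hair inside the open interval: in double
    precision the CDF saturates to exactly 0/1 beyond |raw| ~ 8.3, which
    would put rates on the closed boundary.
    """
    return np.clip(norm.cdf(raw), _RATE_EPS, 1.0 - _RATE_EPS)


def raw_to_params(raw: np.ndarray, variant: ModelVariant) -> np.ndarray:
    """Raw free-parameter vector -> full 9-vector on the model scale.

    Rate-type entries pass through the standard-normal CDF; the rest are
    identity-transformed.
    """
    free = variant.free_params
    vec = np.array([_NEUTRAL[p] for p in PARAM_NAMES])
    for k, p in enumerate(free):
        vec[PARAM_NAMES.index(p)] = norm.cdf(raw[k]) if p in RATE_PARAMS else raw[k]
    return vec


def rate_mask(variant: ModelVariant) -> np.ndarray:
    """Boolean mask over the variant's free parameters marking rate types."""
    return np.array([p in RATE_PARAMS for p in variant.free_params])
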