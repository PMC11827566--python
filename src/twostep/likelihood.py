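"""Sequence log-likelihood of a trial table under any model variant."""

from __future__ import annotations

from typing import Mapping

import numpy as np
import pandas as pd

from . import _core, latent
from .io import pack_dataset
from .task import TaskConfig
from .variants import ModelVariant, ParameterSet, get_variant


def sequence_loglik(trials: pd.DataFrame, params: ParameterSet | Mapping,
                    variant: ModelVariant | str, config: TaskConfig,
                    engine: str = "fast", decay_all: bool = False):
    """Total and pointwise log-likelihood of one subject's trial sequence.

    Each valid trial contributes ``ln P(a1) + ln P(a2)`` given the history up
    to that trial; invalid trials are excluded from the likelihood but still
    advance the sampling counters.  ``engine="reference"`` runs the explicit
    pure-Python recursion in :mod:`twostep.latent` instead of the numba
    kernel (useful for cross-checks).

    Returns ``(total, pointwise)`` where ``pointwise`` has one entry per
    valid trial in order.
    """
    variant = get_variant(variant)
    if isinstance(params, Mapping):
        params = ParameterSet.from_dict(dict(params))
    if len(trials) == 0:
        raise ValueError("empty trial table")
    if trials.subject.nunique() > 1:
        raise ValueError("sequence_loglik expects a single subject's trials")
    packed = pack_dataset(trials, config)

    if engine == "reference":
        return latent.sequence_loglik_reference(
            packed.s1, packed.s2, packed.a2, packed.reward, packed.valid,
            params, variant, packed.common0, packed.p_common, decay_all)
    if engine != "fast":
        raise ValueError("engine must be 'fast' or 'reference'")

    pvec = params.as_vector(variant)
    total, ll, _ = _core.forward_full(
        packed.s1, packed.s2, packed.a2, packed.reward, packed.valid, pvec,
        variant.uses_hop, variant.exploration_code, decay_all,
        packed.p_common, packed.common0)
    return float(total), ll[packed.valid]


def s1_choice_probabilities(trials: pd.DataFrame, params: ParameterSet | Mapping,
                            variant: ModelVariant | str, config: TaskConfig,
                            decay_all: bool = False) -> np.ndarray:
    """One-step-ahead P(a1 = 0) per trial, conditional on the observed history."""
    variant = get_variant(variant)
    if isinstance(params, Mapping):
        params = ParameterSet.from_dict(dict(params))
    packed = pack_dataset(trials, config)
    pvec = params.as_vector(variant)
    _, _, p0 = _core.forward_full(
        packed.s1, packed.s2, packed.a2, packed.reward, packed.valid, pvec,
        variant.uses_hop, variant.exploration_code, decay_all,
        packed.p_common, packed.common0)
    return p0
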