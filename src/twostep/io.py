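"""Reading, validation and filtering of trial tables.

The single interchange format is a tidy CSV with one row per trial:

``subject, trial, s1_action, transition, s2_state, s2_action, reward, rt_ms, valid``

``s1_action``/``s2_action`` are 0/1, ``transition`` is ``common``/``rare``,
``s2_state`` is ``B``/``C``, ``reward`` is 0-100 (magnitude variant) or 0/1
(probability variant), ``rt_ms`` may be empty, ``valid`` is boolean.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task import S2_STATES, TaskConfig

COLUMNS = ["subject", "trial", "s1_action", "transition", "s2_state",
           "s2_action", "reward", "rt_ms", "valid"]

REQUIRED = [c for c in COLUMNS if c not in ("rt_ms", "valid")]


def infer_mapping(table: pd.DataFrame) -> str:
    """Majority-vote the common destination of action 0 from observed
    transitions (the common state is wherever action 0 lands most often)."""
    sub = table[table.s1_action == 0]
    if len(sub) == 0:
        return "B"
    counts = sub.s2_state.value_counts()
    return str(counts.idxmax())


def validate_trial_table(table: pd.DataFrame, config: TaskConfig,
                         mismatch_tol: float = 0.01) -> None:
    """Check schema, value ranges and transition-label consistency.

    Raises ``ValueError`` with a descriptive message on the first violation.
    A fraction of label mismatches up to ``mismatch_tol`` is tolerated (data
    entry noise); beyond that the table is rejected.
    """
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"trial table missing required columns: {missing}")
    if len(table) == 0:
        raise ValueError("trial table is empty")
    for col in ("s1_action", "s2_action"):
        if not table[col].isin([0, 1]).all():
            raise ValueError(f"{col} must be 0 or 1")
    if not table.s2_state.isin(S2_STATES).all():
        raise ValueError("s2_state must be 'B' or 'C'")
    if not table.transition.isin(["common", "rare"]).all():
        raise ValueError("transition must be 'common' or 'rare'")
    r = table.reward.to_numpy(dtype=float)
    if np.isnan(r).any():
        raise ValueError("reward contains NaN values")
    lo, hi = config.walk_bounds if config.is_magnitude else (0.0, 1.0)
    if config.is_magnitude:
        if r.min() < lo or r.max() > hi:
            raise ValueError(f"magnitude rewards must lie in [{lo}, {hi}]")
    else:
        if not np.isin(r, [0.0, 1.0]).all():
            raise ValueError("probability-variant rewards must be binary 0/1")

    # transition labels must match (s1_action, s2_state) under the mapping
    common_state = np.where(table.s1_action.to_numpy() == 0,
                            config.common_state_action0,
                            S2_STATES[1 - config.common0])
    expected = np.where(table.s2_state.to_numpy() == common_state, "common", "rare")
    mismatch = float(np.mean(expected != table.transition.to_numpy()))
    if mismatch > mismatch_tol:
        raise ValueError(
            f"{mismatch:.1%} of transition labels inconsistent with the "
            f"mapping (action 0 common -> {config.common_state_action0})")

    rate = float((table.transition == "common").mean())
    if abs(rate - config.p_common) > 0.10:
        warnings.warn(
            f"observed common-transition rate {rate:.2f} deviates from "
            f"p_common={config.p_common} by more than 10 percentage points",
            stacklevel=2)


def read_trial_table(path, config: TaskConfig,
                     column_map: dict | None = None) -> pd.DataFrame:
    """Read and validate a trial-table CSV.

    ``column_map`` renames non-standard columns (``{"their_name": "ours"}``)
    before validation.  If the config's mapping disagrees with the data, the
    mapping is inferred by majority vote and used for validation.
    """
    table = pd.read_csv(path, comment="#")
    if column_map:
        table = table.rename(columns=column_map)
    missing = [c for c in REQUIRED if c not in table.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if "rt_ms" not in table.columns:
        table["rt_ms"] = np.nan
    if "valid" not in table.columns:
        table["valid"] = True
    table["valid"] = table["valid"].astype(bool)

    inferred = infer_mapping(table)
    if inferred != config.common_state_action0:
        config = TaskConfig(variant=config.variant, n_trials=config.n_trials,
                            p_common=config.p_common,
                            walk_step_sd=config.walk_step_sd,
                            walk_bounds=config.walk_bounds,
                            common_state_action0=inferred, seed=config.seed)
    validate_trial_table(table, config)
    table.attrs["common_state_action0"] = config.common_state_action0
    return table


def write_trial_table(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def filter_trials(table: pd.DataFrame, rt_threshold_ms: float = 150.0):
    """Mark trials faster than the response-time threshold as invalid.

    Trials without a response time are untouched.  Returns the filtered
    table (copy) and a per-subject report of excluded-trial counts.
    Re-applying the filter is a no-op.
    """
    if rt_threshold_ms < 0:
        raise ValueError("rt_threshold_ms must be >= 0")
    table = table.copy()
    if "rt_ms" not in table.columns or table.rt_ms.isna().all():
        if "rt_ms" not in table.columns:
            warnings.warn("no rt_ms column; response-time filter skipped", stacklevel=2)
        report = table.groupby("subject", sort=False).size().rename("n_trials").to_frame()
        report["n_excluded"] = 0
        return table, report.reset_index()
    fast = table.rt_ms.notna() & (table.rt_ms < rt_threshold_ms)
    table.loc[fast, "valid"] = False
    grp = table.groupby("subject", sort=False)
    report = pd.DataFrame({
        "n_trials": grp.size(),
        "n_excluded": grp.apply(lambda g: int((~g.valid).sum()), include_groups=False),
    }).reset_index()
    return table, report


@dataclass
class PackedData:
    """Dataset flattened to contiguous arrays for the numba kernels."""

    subjects: list
    s1: np.ndarray       # int64, first-stage actions
    s2: np.ndarray       # int64, second-stage states (0=B, 1=C)
    a2: np.ndarray       # int64, second-stage actions
    reward: np.ndarray   # float64, unit scale
    valid: np.ndarray    # bool
    offsets: np.ndarray  # int64, (n_subjects + 1,) slice boundaries
    p_common: float
    common0: int

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    @property
    def n_valid(self) -> int:
        return int(self.valid.sum())

    def subject_slice(self, s: int) -> slice:
        return slice(self.offsets[s], self.offsets[s + 1])


def pack_dataset(table: pd.DataFrame, config: TaskConfig) -> PackedData:
    """Flatten a (possibly multi-subject) trial table for kernel use.

    Rewards are rescaled to [0, 1] here (divided by the magnitude range for
    the magnitude variant), so all downstream value updates live on the unit
    scale.
    """
    validate_trial_table(table, config)
    subjects = list(pd.unique(table.subject))
    parts = [table[table.subject == s].sort_values("trial") for s in subjects]
    lengths = [len(p) for p in parts]
    offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
    cat = pd.concat(parts, ignore_index=True)
    scale = config.walk_bounds[1] if config.is_magnitude else 1.0
    return PackedData(
        subjects=subjects,
        s1=cat.s1_action.to_numpy(dtype=np.int64),
        s2=cat.s2_state.map({"B": 0, "C": 1}).to_numpy(dtype=np.int64),
        a2=cat.s2_action.to_numpy(dtype=np.int64),
        reward=cat.reward.to_numpy(dtype=float) / scale,
        valid=cat.valid.to_numpy(dtype=bool) if "valid" in cat.columns
        else np.ones(len(cat), dtype=bool),
        offsets=offsets,
        p_common=config.p_common,
        common0=config.common0,
    )
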