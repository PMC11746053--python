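"""Replicate error propagation into decision-function values.

The DF is linear in each target's Cq, so measuring each of m targets in r
replicates yields r^m equally plausible DF values — one per combination of
replicate choices. Enumerating them all (5 targets × 5 replicates = 3125
combinations) turns the instrument's technical error into an empirical DF
distribution, summarized by its coefficient of variation.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np

from .classifier import LinearClassifier
from .cohort import CQ_CAP
from .errors import CqTriageError, DataError, UndefinedCVError


@dataclass
class ReplicateSet:
    """Per-target replicate Cq lists for one specimen."""

    sample_id: str
    cq: dict  # target -> list of replicate Cq values

    def __post_init__(self):
        for target, values in self.cq.items():
            if len(values) < 1:
                raise DataError(f"target {target!r} has no replicates")
            if any(v > CQ_CAP + 1e-12 or v <= 0 for v in values):
                raise DataError(f"target {target!r} has Cq outside (0, 40]")


@dataclass
class ReplicateSummary:
    sample_id: str
    df_values: np.ndarray
    mean_df: float
    cv_percent: float | None


def coefficient_of_variation(values) -> float:
    """100 × sample SD (n−1 denominator) / |mean|; 0 for a single value."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise DataError("CV of an empty set is undefined")
    mean = values.mean()
    if mean == 0:
        raise UndefinedCVError("CV undefined for zero-mean values")
    if values.size == 1 or np.all(values == values[0]):
        return 0.0
    return float(100.0 * values.std(ddof=1) / abs(mean))


def df_combinations(
    reps: ReplicateSet,
    clf: LinearClassifier,
    max_combinations: int = 10**6,
    sample: int | None = None,
    seed: int = 0,
) -> ReplicateSummary:
    """All-combination DF distribution for one specimen.

    Enumerates the Cartesian product of per-target replicate choices in
    lexicographic order (targets in classifier order, replicate index
    fastest on the last target) and evaluates the DF for each. Products
    larger than ``max_combinations`` raise unless ``sample`` requests a
    seeded Monte-Carlo subsample of that many combinations.
    """
    target_weights = clf.effective_target_weights()
    targets = list(target_weights)
    missing = [t for t in targets if t not in reps.cq]
    if missing:
        raise DataError(f"replicate set lacks classifier targets: {missing}")
    arrays = [np.asarray(reps.cq[t], dtype=float) for t in targets]
    weights = np.array([target_weights[t] for t in targets])
    n_combinations = int(np.prod([len(a) for a in arrays]))
    if sample is None:
        if n_combinations > max_combinations:
            raise CqTriageError(
                f"{n_combinations} combinations exceed the cap "
                f"{max_combinations}; pass sample=N for Monte-Carlo mode"
            )
        df_values = np.fromiter(
            (
                clf.intercept + float(np.dot(weights, combo))
                for combo in itertools.product(*arrays)
            ),
            dtype=float,
            count=n_combinations,
        )
    else:
        rng = np.random.default_rng(seed)
        picks = np.column_stack(
            [rng.integers(0, len(a), size=int(sample)) for a in arrays]
        )
        chosen = np.column_stack([a[picks[:, i]] for i, a in enumerate(arrays)])
        df_values = clf.intercept + chosen @ weights
    mean_df = float(df_values.mean())
    try:
        cv = coefficient_of_variation(df_values)
    except UndefinedCVError:
        cv = None
    return ReplicateSummary(reps.sample_id, df_values, mean_df, cv)
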