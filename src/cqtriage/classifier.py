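"""Linear decision-function classifiers over ΔCq pair features.

A classifier is an ordered pair list with weights and an intercept; applied
to a specimen it emits the dimensionless decision function

    DF = w0 + Σ_i w_i · ΔCq_i

where DF > 0 calls an increased risk of ≥HSIL and the distance from zero
reflects relative risk. Weights are fit by (effectively unpenalized)
logistic regression; the intercept doubles as the diagnostic cutoff and is
re-tuned per screening strategy.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from enum import Enum

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold

from .errors import ConfigurationError, DataError, InfeasibleStrategyError
from .pairs import PairDef


@dataclass
class LinearClassifier:
    pairs: list[PairDef]
    weights: np.ndarray
    intercept: float
    contrast: str | None = None
    strategy: str | None = None

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        if len(self.pairs) < 1:
            raise ConfigurationError("classifier needs at least one pair")
        if len(self.weights) != len(self.pairs):
            raise ConfigurationError("one weight per pair required")
        if not np.all(np.isfinite(self.weights)) or not np.isfinite(self.intercept):
            raise ConfigurationError("weights and intercept must be finite")

    @property
    def pair_names(self) -> list[str]:
        return [p.name for p in self.pairs]

    def effective_target_weights(self) -> dict[str, float]:
        """Net weight on each target's Cq when the DF is expanded.

        DF is linear in the raw Cq values: each pair contributes +w_i to its
        Y target and −w_i to its X target.
        """
        out: dict[str, float] = {}
        for pair, w in zip(self.pairs, self.weights):
            out[pair.y_target] = out.get(pair.y_target, 0.0) + w
            out[pair.x_target] = out.get(pair.x_target, 0.0) - w
        return out

    def df(self, features: pd.DataFrame) -> pd.Series:
        missing = [n for n in self.pair_names if n not in features.columns]
        if missing:
            raise DataError(f"feature matrix lacks pair columns: {missing}")
        values = features[self.pair_names].to_numpy(dtype=float)
        return pd.Series(
            self.intercept + values @ self.weights, index=features.index, name="df"
        )

    # -- serialization -------------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "pairs": [
                {"x": p.x_target, "y": p.y_target, "type": p.pair_type}
                for p in self.pairs
            ],
            "weights": [float(w) for w in self.weights],
            "intercept": float(self.intercept),
            "contrast": self.contrast,
            "strategy": self.strategy,
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_dict(cls, payload: dict) -> "LinearClassifier":
        pairs = [PairDef(p["x"], p["y"], p["type"]) for p in payload["pairs"]]
        return cls(
            pairs,
            np.array(payload["weights"], dtype=float),
            float(payload["intercept"]),
            contrast=payload.get("contrast"),
            strategy=payload.get("strategy"),
        )

    @classmethod
    def load(cls, path) -> "LinearClassifier":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class DecisionResult:
    sample_id: str
    df: float
    call: str  # "low_risk" | "increased_risk"
    borderline: bool


class Strategy(str, Enum):
    """Cutoff-selection strategies for different screening deployments."""

    BASIC = "basic"  # sensitivity ≈ specificity
    HIGH_SENS_ACCEPTABLE_SPEC = "high_sens_acceptable_spec"  # sens > 90, spec ≥ 80
    VERY_HIGH_SENS = "very_high_sens"  # sens ≥ 95 (targeting the 95-99 band)
    HIGH_SPEC_ACCEPTABLE_SENS = "high_spec_acceptable_sens"  # spec > 90, sens ≥ 80
    VERY_HIGH_SPEC = "very_high_spec"  # spec ≥ 95 (targeting the 95-99 band)


def train(
    features: pd.DataFrame,
    labels,
    pairs: list[PairDef] | None = None,
    k_folds: int = 5,
    seed: int = 0,
    contrast: str | None = None,
) -> tuple[LinearClassifier, pd.Series]:
    """Fit a logistic DF classifier and return out-of-fold DF values.

    The final weights are refit on all samples; the returned per-sample DF
    values come from stratified K-fold cross-validation (each sample scored
    by the model that did not see it) for unbiased downstream evaluation.
    Regularization is negligible (C = 1e8): the DF is an unconstrained
    linear score. Deterministic given ``seed``.
    """
    labels = pd.Series(labels, index=features.index).astype(int)
    if pairs is None:
        from .pairs import PairDef as _PD

        pairs = []
        for name in features.columns:
            x, _, y = name.partition("-")
            pairs.append(_PD(x, y, "??"))
    names = [p.name for p in pairs]
    X = features[names].to_numpy(dtype=float)
    y = labels.to_numpy()
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise DataError("training requires both classes present")
    if counts.min() < 2:
        raise DataError("training requires at least 2 samples per class")
    k_folds = int(k_folds)
    if k_folds > counts.min():
        raise ConfigurationError(
            f"k_folds={k_folds} exceeds the smaller class size {counts.min()}"
        )

    def _fit(Xf, yf) -> LogisticRegression:
        model = LogisticRegression(C=1e8, solver="lbfgs", max_iter=10_000)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(Xf, yf)
        return model

    oof = np.full(len(y), np.nan)
    splitter = StratifiedKFold(n_splits=k_folds, shuffle=True, random_state=seed)
    for train_idx, test_idx in splitter.split(X, y):
        fold_model = _fit(X[train_idx], y[train_idx])
        oof[test_idx] = fold_model.decision_function(X[test_idx])

    final = _fit(X, y)
    if np.abs(final.coef_).max() > 50:
        warnings.warn(
            "near-perfect separation: weights converged to a large-margin "
            "solution and are scale-unstable",
            stacklevel=2,
        )
    clf = LinearClassifier(
        list(pairs),
        final.coef_.ravel().copy(),
        float(final.intercept_[0]),
        contrast=contrast,
    )
    return clf, pd.Series(oof, index=features.index, name="df_oof")


def flag_borderline(df: float, df_values, fraction: float = 0.10) -> bool:
    """Gray-zone flag: DF within 10% of the observed values above and below
    the cutoff.

    The cutoff is DF = 0 (the intercept is tuned so the operating threshold
    maps there). Each side of the cutoff is scaled by its own observed
    extent: a positive DF is borderline when it lies within 10% of the
    maximum observed DF, a negative one within 10% of the minimum. With a
    degenerate range (all DF equal) nothing is flagged.
    """
    df_values = np.asarray(df_values, dtype=float)
    if df_values.size == 0:
        raise DataError("flag_borderline needs a non-empty DF reference set")
    if df_values.max() == df_values.min():
        warnings.warn("degenerate DF range; borderline flag disabled", stacklevel=2)
        return False
    upper = fraction * max(df_values.max(), 0.0)
    lower = fraction * min(df_values.min(), 0.0)
    return bool(lower <= df <= upper)


def decision_function(
    clf: LinearClassifier,
    features: pd.DataFrame,
    reference_df=None,
) -> list[DecisionResult]:
    """Score samples: DF value, risk call (DF > 0 ⇒ increased risk), gray zone.

    ``reference_df`` supplies the DF distribution used for the borderline
    flag; by default the scored cohort's own DF values.
    """
    df = clf.df(features)
    ref = df.to_numpy() if reference_df is None else np.asarray(reference_df, float)
    degenerate = ref.size == 0 or (ref.max() - ref.min()) == 0
    results = []
    for sid, value in df.items():
        call = "increased_risk" if value > 0 else "low_risk"
        borderline = False if degenerate else flag_borderline(value, ref)
        results.append(DecisionResult(sid, float(value), call, borderline))
    return results


def _operating_points(df_values: np.ndarray, labels: np.ndarray):
    """Candidate cutoffs (midpoints between sorted distinct DFs plus ±inf)
    with their (sensitivity, specificity) in percent, strict > call rule."""
    distinct = np.unique(df_values)
    candidates = [-np.inf]
    candidates += list((distinct[:-1] + distinct[1:]) / 2.0)
    candidates.append(np.inf)
    pos = labels == 1
    n_pos = pos.sum()
    n_neg = (~pos).sum()
    points = []
    for cut in candidates:
        called = df_values > cut
        sens = 100.0 * (called & pos).sum() / n_pos
        spec = 100.0 * (~called & ~pos).sum() / n_neg
        points.append((cut, sens, spec))
    return points


_STRATEGY_RULES = {
    Strategy.HIGH_SENS_ACCEPTABLE_SPEC: (
        lambda sens, spec: sens > 90.0 and spec >= 80.0,
        lambda sens, spec: spec,
    ),
    Strategy.VERY_HIGH_SENS: (
        lambda sens, spec: sens >= 95.0,
        lambda sens, spec: spec,
    ),
    Strategy.HIGH_SPEC_ACCEPTABLE_SENS: (
        lambda sens, spec: spec > 90.0 and sens >= 80.0,
        lambda sens, spec: sens,
    ),
    Strategy.VERY_HIGH_SPEC: (
        lambda sens, spec: spec >= 95.0,
        lambda sens, spec: sens,
    ),
}


def tune_cutoff(
    clf: LinearClassifier, df_values, labels, strategy
) -> LinearClassifier:
    """Re-anchor the intercept so the strategy's operating threshold is DF = 0.

    Scans every achievable operating point (midpoints between consecutive
    sorted DF values plus ±∞). The ``basic`` strategy minimizes
    |sens − spec|; constrained strategies keep only feasible points and
    maximize the unconstrained metric (specificity for sensitivity-bound
    strategies and vice versa). Ties break toward higher specificity.
    """
    strategy = Strategy(strategy)
    df_values = np.asarray(df_values, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if labels.min() == labels.max():
        raise DataError("cutoff tuning requires both classes present")
    points = _operating_points(df_values, labels)

    if strategy is Strategy.BASIC:
        eligible = points
        objective = lambda sens, spec: -abs(sens - spec)
    else:
        feasible, objective = _STRATEGY_RULES[strategy]
        eligible = [p for p in points if feasible(p[1], p[2])]
        if not eligible:
            best = max(points, key=lambda p: objective(p[1], p[2]))
            raise InfeasibleStrategyError(
                f"no cutoff satisfies strategy {strategy.value!r}; best "
                f"attainable operating point: sens {best[1]:.1f}%, "
                f"spec {best[2]:.1f}%",
                best_operating_point=(best[1], best[2]),
            )
    best = max(eligible, key=lambda p: (objective(p[1], p[2]), p[2]))
    cut = best[0]
    if not np.isfinite(cut):
        # all-or-nothing threshold: anchor just outside the observed range
        span = max(df_values.max() - df_values.min(), 1.0)
        cut = df_values.min() - 0.05 * span if cut == -np.inf else df_values.max() + 0.05 * span
    tuned = LinearClassifier(
        clf.pairs,
        clf.weights.copy(),
        clf.intercept - float(cut),
        contrast=clf.contrast,
        strategy=strategy.value,
    )
    return tuned
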