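"""Training, decision functions, cutoff strategies and the gray zone."""

import numpy as np
import pandas as pd
import pytest

from cqtriage import (
    LinearClassifier,
    decision_function,
    feature_matrix,
    flag_borderline,
    roc_auc,
    train,
    tune_cutoff,
)
from cqtriage.classifier import _operating_points
from cqtriage.errors import DataError, InfeasibleStrategyError
from cqtriage.pairs import PairDef

PAIRS = [PairDef("B", "A", "DU"), PairDef("C", "A", "DU")]


def _features(X):
    return pd.DataFrame(X, columns=[p.name for p in PAIRS])


class TestTrain:
    def test_separable_cohort_reaches_training_auc_one(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(-3, 0.5, (30, 2)), rng.normal(3, 0.5, (30, 2))])
        y = np.repeat([0, 1], 30)
        clf, _ = train(_features(X), y, pairs=PAIRS, seed=0)
        assert roc_auc(clf.df(_features(X)), y) == 1.0

    def test_single_class_rejected(self):
        X = np.random.default_rng(0).normal(size=(10, 2))
        with pytest.raises(DataError):
            train(_features(X), np.zeros(10, dtype=int), pairs=PAIRS, seed=0)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 2))
        y = (X.sum(axis=1) + rng.normal(size=60) > 0).astype(int)
        out1 = train(_features(X), y, pairs=PAIRS, seed=7)
        out2 = train(_features(X), y, pairs=PAIRS, seed=7)
        assert np.allclose(out1[0].weights, out2[0].weights)
        assert out1[1].equals(out2[1])


class TestDecisionFunction:
    def test_zero_classifier_calls_low_risk(self):
        clf = LinearClassifier(PAIRS, [0.0, 0.0], 0.0)
        results = decision_function(clf, _features(np.ones((3, 2))))
        assert all(r.df == 0.0 and r.call == "low_risk" for r in results)

    def test_reference_worked_example(self, ref_cohort, ref_classifier, classifier1_pairs, ref_df):
        """Recovered weights reproduce the published DF values and risk calls."""
        features = feature_matrix(ref_cohort, classifier1_pairs)
        results = {r.sample_id: r for r in decision_function(ref_classifier, features)}
        assert results["HSIL-1"].df == pytest.approx(0.5122, abs=0.005)
        assert results["HSIL-1"].call == "increased_risk"
        assert results["HeLa"].df == pytest.approx(3.8160, abs=0.005)
        for sid, expected in ref_df.items():
            call = "increased_risk" if expected > 0 else "low_risk"
            assert results[sid].call == call

    def test_affine_in_each_feature(self, ref_classifier):
        rng = np.random.default_rng(5)
        base = pd.DataFrame(
            rng.normal(size=(4, 4)), columns=ref_classifier.pair_names
        )
        df0 = ref_classifier.df(base)
        for i, name in enumerate(ref_classifier.pair_names):
            shifted = base.copy()
            shifted[name] += 1.7
            np.testing.assert_allclose(
                ref_classifier.df(shifted) - df0, 1.7 * ref_classifier.weights[i]
            )

    def test_orientation_invariance(self, ref_cohort, ref_classifier, classifier1_pairs):
        """Flipping a pair's orientation and negating its weight leaves DF unchanged."""
        features = feature_matrix(ref_cohort, classifier1_pairs)
        flipped_pairs = [classifier1_pairs[0].swapped()] + classifier1_pairs[1:]
        flipped_weights = ref_classifier.weights.copy()
        flipped_weights[0] *= -1
        flipped = LinearClassifier(flipped_pairs, flipped_weights, ref_classifier.intercept)
        flipped_features = feature_matrix(ref_cohort, flipped_pairs)
        np.testing.assert_allclose(
            flipped.df(flipped_features), ref_classifier.df(features)
        )


class TestTuneCutoff:
    DF = np.array([-2.0, -1.0, 1.0, 2.0])
    Y = np.array([0, 0, 1, 1])

    def test_very_high_spec_on_separable_data(self):
        clf = LinearClassifier(PAIRS, [1.0, 1.0], 0.0)
        tuned = tune_cutoff(clf, self.DF, self.Y, "very_high_spec")
        # chosen threshold lies in (-1, 1): sens and spec both 100%
        shift = clf.intercept - tuned.intercept
        assert -1.0 < shift < 1.0

    def test_basic_minimizes_sens_spec_gap(self):
        rng = np.random.default_rng(2)
        df = np.concatenate([rng.normal(-1, 1, 80), rng.normal(1, 1, 80)])
        y = np.repeat([0, 1], 80)
        clf = LinearClassifier(PAIRS, [1.0, 1.0], 0.0)
        tuned = tune_cutoff(clf, df, y, "basic")
        cut = clf.intercept - tuned.intercept
        gaps = [abs(s - p) for _, s, p in _operating_points(df, y)]
        called = df > cut
        sens = 100 * (called & (y == 1)).sum() / 80
        spec = 100 * (~called & (y == 0)).sum() / 80
        assert abs(sens - spec) == pytest.approx(min(gaps))

    def test_infeasible_strategy_reports_best_point(self):
        df = np.array([0.0, 1.0, 0.0, 1.0, 0.0, 1.0])
        y = np.array([1, 0, 1, 0, 1, 0])  # anti-separated
        clf = LinearClassifier(PAIRS, [1.0, 1.0], 0.0)
        with pytest.raises(InfeasibleStrategyError) as err:
            tune_cutoff(clf, df, y, "high_sens_acceptable_spec")
        assert err.value.best_operating_point is not None

    def test_monotone_sens_spec_tradeoff(self):
        rng = np.random.default_rng(9)
        df = rng.normal(size=50)
        y = (rng.uniform(size=50) < 0.5).astype(int)
        points = _operating_points(df, y)
        sens = [p[1] for p in points]
        spec = [p[2] for p in points]
        assert all(a >= b for a, b in zip(sens, sens[1:]))
        assert all(a <= b for a, b in zip(spec, spec[1:]))


class TestBorderline:
    def test_cutoff_value_is_borderline(self):
        assert flag_borderline(0.0, [-1.0, 1.0])

    def test_extreme_value_is_not(self):
        assert not flag_borderline(1.0, [-1.0, 1.0])

    @pytest.mark.parametrize("df,expected", [(0.15, False), (0.05, True)])
    def test_ten_percent_of_range_rule(self, df, expected):
        assert flag_borderline(df, [-1.0, 1.0]) is expected

    def test_degenerate_range_warns_and_disables(self):
        with pytest.warns(UserWarning):
            assert flag_borderline(0.0, [1.0, 1.0]) is False


def test_serialization_round_trip(tmp_path, ref_classifier):
    path = tmp_path / "clf.json"
    ref_classifier.save(path)
    back = LinearClassifier.load(path)
    assert back.pair_names == ref_classifier.pair_names
    np.testing.assert_array_equal(back.weights, ref_classifier.weights)
    assert back.intercept == ref_classifier.intercept
    assert back.contrast == ref_classifier.contrast
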