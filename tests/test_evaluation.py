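"""Diagnostic statistics: AUC, exact binomial CIs, rank tests, summaries."""

import numpy as np
import pytest

from cqtriage import (
    auc_ci,
    bonferroni_threshold,
    clopper_pearson,
    group_summary,
    mann_whitney,
    roc_auc,
    sens_spec,
    spearman,
)
from cqtriage.errors import DataError, UndefinedCorrelationError


class TestRocAuc:
    @pytest.mark.parametrize(
        "scores,labels,expected",
        [
            ((1, 2, 3, 4), (0, 0, 1, 1), 1.0),
            ((5, 5, 5, 5), (0, 0, 1, 1), 0.5),
            ((1, 2, 2, 3), (0, 0, 1, 1), 0.875),  # ties count one half
        ],
    )
    def test_small_examples(self, scores, labels, expected):
        assert roc_auc(scores, labels) == pytest.approx(expected)

    def test_single_class_rejected(self):
        with pytest.raises(DataError):
            roc_auc([1, 2], [1, 1])

    def test_matches_sklearn_on_random_data(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(4, 60)
            scores = rng.integers(0, 10, size=n).astype(float)
            labels = rng.integers(0, 2, size=n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores)
            )


class TestAucCI:
    def test_perfect_separation_upper_bound_clipped(self):
        scores = np.concatenate([np.zeros(50), np.ones(50)])
        labels = np.repeat([0, 1], 50)
        with pytest.warns(UserWarning):
            lo, hi = auc_ci(scores, labels)
        assert hi == 1.0

    def test_interval_widens_with_level(self):
        rng = np.random.default_rng(4)
        scores = np.concatenate([rng.normal(0, 1, 200), rng.normal(1.19, 1, 200)])
        labels = np.repeat([0, 1], 200)
        widths = []
        for level in (0.90, 0.95, 0.99):
            lo, hi = auc_ci(scores, labels, level)
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_brackets_point_estimate(self):
        rng = np.random.default_rng(8)
        scores = rng.normal(size=80)
        labels = (rng.uniform(size=80) < 0.4).astype(int)
        lo, hi = auc_ci(scores, labels)
        assert lo <= roc_auc(scores, labels) <= hi


class TestClopperPearson:
    @pytest.mark.parametrize(
        "successes,trials,expected",
        [
            (70, 78, (80.79, 95.47)),  # published sensitivity CI at 89.74%
            (78, 89, (78.96, 93.67)),  # published specificity CI at 87.64%
        ],
    )
    def test_reproduces_published_intervals(self, successes, trials, expected):
        lo, hi = clopper_pearson(successes, trials)
        assert (round(lo, 2), round(hi, 2)) == expected

    def test_zero_successes_lower_bound_zero(self):
        lo, hi = clopper_pearson(0, 10)
        assert lo == 0.0 and 0 < hi < 100

    def test_all_successes_upper_bound_hundred(self):
        assert clopper_pearson(10, 10)[1] == 100.0


class TestSensSpec:
    def test_cutoff_below_everything(self):
        m = sens_spec([1, 2, 3, 4], [0, 0, 1, 1], cutoff=0.0)
        assert m.sensitivity == 100.0 and m.specificity == 0.0

    def test_cutoff_above_everything(self):
        m = sens_spec([1, 2, 3, 4], [0, 0, 1, 1], cutoff=10.0)
        assert m.sensitivity == 0.0 and m.specificity == 100.0

    def test_published_operating_point(self):
        """70 of 78 positives above, 78 of 89 negatives below the cutoff."""
        scores = np.concatenate(
            [np.ones(70), -np.ones(8), -np.ones(78), np.ones(11)]
        )
        labels = np.concatenate([np.ones(78), np.zeros(89)]).astype(int)
        m = sens_spec(scores, labels, cutoff=0.0)
        assert m.sensitivity == pytest.approx(89.74, abs=0.01)
        assert m.specificity == pytest.approx(87.64, abs=0.01)
        assert (m.tp, m.fn, m.tn, m.fp) == (70, 8, 78, 11)
        assert round(m.sensitivity_ci[0], 2) == 80.79


class TestMannWhitney:
    def test_identical_groups_p_one(self):
        res = mann_whitney([1, 1, 1], [1, 1, 1])
        assert res.p_value == 1.0

    def test_exact_enumeration_small_groups(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u_statistic == 0.0
        assert res.p_value == pytest.approx(0.1)  # 2 / C(6,3)

    def test_u_auc_identity(self):
        rng = np.random.default_rng(1)
        a = rng.normal(1, 1, 40)
        b = rng.normal(0, 1, 30)
        res = mann_whitney(a, b)
        pooled = np.concatenate([a, b])
        labels = np.concatenate([np.ones(40), np.zeros(30)]).astype(int)
        assert res.u_statistic / (40 * 30) == pytest.approx(roc_auc(pooled, labels))


class TestBonferroni:
    @pytest.mark.parametrize(
        "alpha,n,expected",
        [(0.05, 16, 0.003125), (0.05, 21, 0.05 / 21), (0.05, 1, 0.05)],
    )
    def test_threshold_values(self, alpha, n, expected):
        assert bonferroni_threshold(alpha, n) == pytest.approx(expected)

    def test_decreasing_in_comparisons(self):
        values = [bonferroni_threshold(0.05, n) for n in range(1, 30)]
        assert all(a > b for a, b in zip(values, values[1:]))


class TestSpearman:
    def test_monotone_sequences(self):
        assert spearman([1, 2, 3], [10, 20, 30]).spearman_rs == 1.0
        assert spearman([1, 2, 3], [30, 20, 10]).spearman_rs == -1.0

    def test_hand_computed_rank_example(self):
        assert spearman([1, 2, 3, 4], [1, 3, 2, 4]).spearman_rs == pytest.approx(0.8)

    def test_constant_vector_rejected(self):
        with pytest.raises(UndefinedCorrelationError):
            spearman([1, 1, 1], [1, 2, 3])


class TestGroupSummary:
    def test_hpv_positivity_pooled_percentage(self):
        rows = group_summary(
            [16, 16, 31, 30, 11, 7],
            [60, 22, 32, 33, 13, 7],
            ["NILM", "LSIL", "HSIL", "CC", "FN", "FP"],
        )
        assert rows[-1] == ("pooled", 111, 167, 66.5)

    def test_multigenotype_pooled_percentage(self):
        rows = group_summary([7, 5, 10, 11, 4, 6], [16, 16, 31, 30, 11, 7])
        assert rows[-1][3] == 38.7

    def test_zero_positives(self):
        assert group_summary([0], [10])[0][3] == 0.0

    def test_zero_total_undefined(self):
        assert group_summary([0], [0])[0][3] is None
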