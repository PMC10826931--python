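"""AUROC/DeLong, confusion, importance, parity, and ICC against oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from emsflags.matrix import FeatureMatrix
from emsflags.metrics import (
    auroc,
    confusion_at_threshold,
    delong_ci,
    icc,
    parity_tests,
    two_proportion_test,
    variable_importance,
)


def pairwise_auroc(scores, labels):
    """Exhaustive Mann-Whitney oracle over all positive x negative pairs."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = sum(
        1.0 if p > n else (0.5 if p == n else 0.0) for p in pos for n in neg
    )
    return wins / (len(pos) * len(neg))


def delong_variance_oracle(scores, labels):
    """Naive double-loop structural components."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]

    def psi(x, y):
        return 1.0 if x > y else (0.5 if x == y else 0.0)

    v10 = np.array([np.mean([psi(x, y) for y in neg]) for x in pos])
    v01 = np.array([np.mean([psi(x, y) for x in pos]) for y in neg])
    return np.var(v10, ddof=1) / len(pos) + np.var(v01, ddof=1) / len(neg)


class TestAuroc:
    def test_perfect_ordering(self):
        assert auroc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_all_ties(self):
        assert auroc([0.5] * 8, [0, 1] * 4) == 0.5

    def test_single_class_error(self):
        with pytest.raises(ValueError, match="both classes"):
            auroc([0.1, 0.9], [1, 1])

    def test_matches_pairwise_oracle_randomized(self, rng):
        for _ in range(50):
            n = int(rng.integers(10, 31))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], size=n)
            labels = np.r_[1, 0, rng.integers(0, 2, size=n - 2)]
            assert auroc(scores, labels) == pytest.approx(
                pairwise_auroc(scores, labels), abs=1e-12
            )

    def test_score_negation_flips_auc(self, rng):
        scores = rng.normal(size=40)  # continuous, ties a.s. absent
        labels = np.r_[np.ones(20), np.zeros(20)].astype(int)
        assert auroc(-scores, labels) == pytest.approx(
            1 - auroc(scores, labels), abs=1e-12
        )


class TestDelong:
    def test_perfect_separation_zero_width_ci(self):
        roc = delong_ci([0.9, 0.8, 0.1, 0.2], [1, 1, 0, 0])
        assert roc.auc == 1.0
        assert roc.variance == 0.0
        assert roc.ci == (1.0, 1.0)

    def test_variance_matches_double_loop_oracle(self, rng):
        for _ in range(20):
            scores = rng.choice([0.1, 0.4, 0.4, 0.6, 0.9], size=40)
            labels = np.r_[np.ones(15), np.zeros(25)].astype(int)
            rng.shuffle(labels)
            if labels[:1].sum() >= 0:  # always true; keeps loop simple
                roc = delong_ci(scores, labels)
                assert roc.variance == pytest.approx(
                    delong_variance_oracle(scores, labels), abs=1e-12
                )

    def test_monotone_transform_invariance(self, rng):
        scores = rng.normal(size=60)
        labels = rng.integers(0, 2, size=60)
        labels[:2] = [0, 1]
        a = delong_ci(scores, labels)
        b = delong_ci(np.exp(scores), labels)  # strictly monotone
        assert a.auc == pytest.approx(b.auc, abs=1e-12)
        assert a.variance == pytest.approx(b.variance, abs=1e-12)

    def test_ci_truncated_to_unit_interval(self):
        roc = delong_ci([0.9, 0.8, 0.7, 0.1, 0.2, 0.75], [1, 1, 1, 0, 0, 0])
        assert 0.0 <= roc.ci[0] <= roc.auc <= roc.ci[1] <= 1.0

    def test_min_class_size(self):
        with pytest.raises(ValueError, match="at least 2"):
            delong_ci([0.9, 0.1, 0.2], [1, 0, 0])


class TestConfusion:
    def test_study_sized_cells(self):
        # 54 predicted-and-true positives, 8 false alarms, 44 misses,
        # 486 true negatives: the held-out evaluation shape
        scores = np.r_[np.full(54, 0.9), np.full(8, 0.9),
                       np.full(44, 0.1), np.full(486, 0.1)]
        labels = np.r_[np.ones(54), np.zeros(8), np.ones(44), np.zeros(486)]
        ct = confusion_at_threshold(scores, labels, 0.5)
        assert (ct.tn, ct.fp, ct.fn, ct.tp) == (486, 8, 44, 54)
        assert ct.total == 592
        assert ct.ppv == pytest.approx(54 / 62)
        assert ct.sensitivity == pytest.approx(54 / 98)

    def test_threshold_zero_all_positive(self):
        ct = confusion_at_threshold([0.2, 0.6], [0, 1], threshold=0.0)
        assert ct.fp == 1 and ct.tp == 1 and ct.specificity == 0.0

    def test_undefined_ratio_reported_unknown(self):
        ct = confusion_at_threshold([0.1, 0.2], [0, 0], threshold=0.5)
        assert ct.ppv is None and ct.sensitivity is None

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(
        scores=st.lists(st.floats(0, 1), min_size=1, max_size=30),
        threshold=st.floats(0, 1),
    )
    def test_cells_always_sum_to_n(self, scores, threshold):
        labels = [i % 2 for i in range(len(scores))]
        ct = confusion_at_threshold(scores, labels, threshold)
        assert ct.total == len(scores)


class TestImportance:
    def test_label_column_ranks_first(self):
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        fm = FeatureMatrix(
            [str(i) for i in range(20)],
            ["exact", "constant", "noise"],
            np.column_stack([labels, np.ones(20), np.r_[np.zeros(10), np.ones(10)]]),
        )
        report = variable_importance(fm, labels)
        by_col = {e["column"]: e for e in report.entries}
        assert by_col["exact"]["score"] == 1.0 and by_col["exact"]["rank"] == 1
        assert by_col["constant"]["score"] == 0.5

    def test_reversed_column_scores_high(self):
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        fm = FeatureMatrix(
            [str(i) for i in range(20)], ["reversed"],
            (1 - labels)[:, None].astype(float),
        )
        e = variable_importance(fm, labels).entries[0]
        assert e["auc"] == 0.0 and e["score"] == 1.0

    def test_noisy_column_matches_pairwise_oracle(self, rng):
        labels = rng.integers(0, 2, size=1000)
        labels[:2] = [0, 1]
        col = labels ^ (rng.random(1000) < 0.1)
        fm = FeatureMatrix([str(i) for i in range(1000)], ["noisy"],
                           col[:, None].astype(float))
        e = variable_importance(fm, labels).entries[0]
        assert e["auc"] == pytest.approx(pairwise_auroc(col, labels), abs=1e-12)

    def test_ranks_unique_with_name_tiebreak(self):
        labels = np.r_[np.ones(5), np.zeros(5)].astype(int)
        vals = np.column_stack([labels, labels]).astype(float)
        fm = FeatureMatrix([str(i) for i in range(10)], ["b", "a"], vals)
        report = variable_importance(fm, labels)
        assert [e["column"] for e in report.entries] == ["a", "b"]
        assert [e["rank"] for e in report.entries] == [1, 2]


class TestParity:
    def test_identical_proportions_p_one(self):
        stat, p = two_proportion_test(8, 200, 8, 200)
        assert stat == 0.0 and p == 1.0

    def test_equal_rates_equal_n_not_significant(self):
        report = parity_tests({"male": (20, 200), "female": (20, 200)})
        assert report.pairwise[0]["p_value"] >= 0.99

    def test_matches_closed_form_chi_square(self):
        # hand-computed: x1=30/150 vs x2=12/150, Yates corrected
        x1, n1, x2, n2 = 30, 150, 12, 150
        stat, p = two_proportion_test(x1, n1, x2, n2)
        p_pool = (x1 + x2) / (n1 + n2)
        expected = np.array(
            [[n1 * p_pool, n1 * (1 - p_pool)], [n2 * p_pool, n2 * (1 - p_pool)]]
        )
        observed = np.array([[x1, n1 - x1], [x2, n2 - x2]])
        dev = np.abs(observed - expected) - 0.5
        manual = float(np.sum(dev**2 / expected))
        assert stat == pytest.approx(manual, abs=1e-12)

    def test_large_gender_gap_is_significant(self):
        # rates shaped like the reported male/female false-negative gap
        report = parity_tests({"male": (36, 315), "female": (4, 123)})
        assert report.pairwise[0]["p_value"] < 0.05

    def test_zero_denominator_group_excluded(self):
        report = parity_tests({"a": (1, 50), "b": (2, 60), "c": (0, 0)})
        assert report.excluded == ["c"]
        assert len(report.pairwise) == 1

    def test_fewer_than_two_groups_error(self):
        with pytest.raises(ValueError, match="two groups"):
            parity_tests({"a": (1, 50), "c": (0, 0)})

    def test_null_type_one_error_conservative(self, rng):
        # two groups, true rate 0.10, n=500 each; Yates keeps the
        # rejection rate at alpha=0.05 at or below nominal
        reps = 1000
        x1 = rng.binomial(500, 0.10, size=reps)
        x2 = rng.binomial(500, 0.10, size=reps)
        rejections = sum(
            two_proportion_test(int(a), 500, int(b), 500)[1] < 0.05
            for a, b in zip(x1, x2)
        )
        assert rejections / reps <= 0.06


class TestIcc:
    def test_identical_raters_icc_one(self):
        ratings = np.column_stack([np.arange(6), np.arange(6)])
        result = icc(ratings)
        assert result.icc_value == pytest.approx(1.0)

    def test_hand_computed_six_by_two(self):
        ratings = np.array(
            [[9, 2], [1, 10], [8, 8], [2, 6], [10, 6], [9, 9]], dtype=float
        )
        # independent spreadsheet-style ANOVA oracle
        n, k = ratings.shape
        grand = ratings.mean()
        msr = k * np.sum((ratings.mean(axis=1) - grand) ** 2) / (n - 1)
        msc = n * np.sum((ratings.mean(axis=0) - grand) ** 2) / (k - 1)
        sse = (
            np.sum((ratings - grand) ** 2)
            - msr * (n - 1)
            - msc * (k - 1)
        )
        mse = sse / ((n - 1) * (k - 1))
        expected = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
        result = icc(ratings)
        assert result.icc_value == pytest.approx(expected, abs=1e-12)

    def test_matches_pingouin_icc2(self):
        pingouin = pytest.importorskip("pingouin")
        import pandas as pd

        rng = np.random.default_rng(8)
        ratings = rng.normal(size=(12, 3)) + rng.normal(size=(12, 1))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(12), 3),
                "rater": np.tile(np.arange(3), 12),
                "score": ratings.ravel(),
            }
        )
        ref = pingouin.intraclass_corr(
            long, targets="subject", raters="rater", ratings="score"
        )
        mask = ref["Type"].isin(["ICC2", "ICC(A,1)"])
        icc2 = float(ref.loc[mask, "ICC"].iloc[0])
        assert icc(ratings).icc_value == pytest.approx(icc2, abs=1e-9)

    def test_constant_matrix_reported_unknown(self):
        result = icc(np.full((6, 2), 3.0))
        assert result.icc_value is None
        assert "undefined" in result.note

    def test_input_validation(self):
        with pytest.raises(ValueError, match="raters"):
            icc(np.zeros((6, 1)))
        with pytest.raises(ValueError, match="subjects"):
            icc(np.zeros((3, 2)))
        bad = np.ones((6, 2))
        bad[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            icc(bad)
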