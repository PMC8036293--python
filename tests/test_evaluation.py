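"""Confusion bookkeeping, detection metrics, k-fold, correlation, agreement."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats

from kerato3d.errors import Kerato3dError, UndefinedMetricError
from kerato3d.evaluation import (
    bland_altman,
    confusion,
    kfold_evaluate,
    kfold_split,
    metrics,
    pearson_r,
)

#: 4-class detection counts of a published 268-case study (rows = actual,
#: cols = predicted, order mild/moderate/severe/normal) used as a fixed
#: regression fixture throughout.
STUDY_COUNTS = np.array(
    [
        [48, 2, 0, 8],
        [2, 66, 2, 0],
        [0, 0, 40, 0],
        [2, 2, 0, 96],
    ]
)


def labels_from_counts(counts: np.ndarray, classes) -> tuple[list[str], list[str]]:
    actual, predicted = [], []
    for i, a in enumerate(classes):
        for j, p in enumerate(classes):
            actual += [a] * counts[i, j]
            predicted += [p] * counts[i, j]
    return actual, predicted


class TestConfusion:
    def test_perfect_predictions_diagonal(self):
        labels = ["mild", "moderate", "severe", "normal"] * 3
        cm = confusion(labels, labels)
        assert np.trace(cm.counts) == 12
        assert cm.fp == 0 and cm.fn == 0
        assert cm.accuracy_multiclass == 100.0

    def test_study_row_totals(self):
        actual, predicted = labels_from_counts(
            STUDY_COUNTS, ("mild", "moderate", "severe", "normal")
        )
        cm = confusion(actual, predicted)
        assert list(cm.row_totals) == [58, 70, 40, 100]
        assert cm.counts.sum() == 268
        assert cm.tn == 96 and cm.fp == 4
        assert cm.fn == 8  # keratoconus cases predicted normal: 8 + 0 + 0

    def test_both_tp_conventions(self):
        actual, predicted = labels_from_counts(
            STUDY_COUNTS, ("mild", "moderate", "severe", "normal")
        )
        cm = confusion(actual, predicted)
        assert list(cm.tp_diagonal) == [48, 66, 40, 96]
        assert list(cm.tp_row_minus_normal) == [50, 70, 40, 96]

    def test_order_invariance(self):
        actual = ["mild", "severe", "normal", "mild", "moderate"]
        predicted = ["mild", "severe", "mild", "normal", "moderate"]
        cm1 = confusion(actual, predicted)
        perm = np.random.default_rng(0).permutation(len(actual))
        cm2 = confusion([actual[i] for i in perm], [predicted[i] for i in perm])
        np.testing.assert_array_equal(cm1.counts, cm2.counts)

    def test_unknown_label_rejected(self):
        with pytest.raises(Kerato3dError):
            confusion(["mild"], ["keratoglobus"])


class TestMetrics:
    def test_perfect_counts(self):
        m = metrics(TP=10, TN=5, FP=0, FN=0)
        assert m.accuracy == m.sensitivity == m.specificity == 100.0

    def test_zero_tp_with_fp(self):
        assert metrics(TP=0, TN=5, FP=3, FN=1).sensitivity == 0.0

    def test_zero_denominator_raises(self):
        with pytest.raises(UndefinedMetricError):
            metrics(TP=0, TN=5, FP=0, FN=1)

    def test_literal_vs_textbook_forms(self):
        m = metrics(TP=80, TN=40, FP=10, FN=20)
        assert m.sensitivity == pytest.approx(100 * 80 / 90)
        assert m.recall == pytest.approx(100 * 80 / 100)
        assert m.specificity == pytest.approx(100 * 40 / 60)
        assert m.specificity_tn_fp == pytest.approx(100 * 40 / 50)


class TestKfold:
    def test_268_cases_k10_partition(self):
        labels = ["mild"] * 58 + ["moderate"] * 70 + ["severe"] * 40 + ["normal"] * 100
        folds = kfold_split(labels, k=10, seed=1)
        test_sets = [set(te) for _, te in folds]
        sizes = sorted(len(s) for s in test_sets)
        assert all(26 <= n <= 27 for n in sizes)
        union = set().union(*test_sets)
        assert union == set(range(268))
        assert sum(len(s) for s in test_sets) == 268  # each case exactly once

    def test_leave_one_out_single_class(self):
        labels = ["normal"] * 7
        folds = kfold_split(labels, k=7, seed=0)
        assert all(len(te) == 1 for _, te in folds)

    def test_same_seed_identical_splits(self):
        labels = ["mild", "normal"] * 20
        a = kfold_split(labels, 4, seed=9)
        b = kfold_split(labels, 4, seed=9)
        for (tr1, te1), (tr2, te2) in zip(a, b):
            np.testing.assert_array_equal(te1, te2)

    def test_class_smaller_than_k_rejected(self):
        with pytest.raises(Kerato3dError):
            kfold_split(["mild"] * 3 + ["normal"] * 20, k=5, seed=0)

    def test_training_set_independent_classifier_matches_plain_accuracy(self):
        """With a fixed classifier and equal fold sizes, the k-fold mean
        accuracy equals plain accuracy."""
        rng = np.random.default_rng(4)
        labels = (["mild"] * 10 + ["moderate"] * 10 + ["severe"] * 10
                  + ["normal"] * 10)
        cases = list(range(40))
        fixed_pred = {i: (labels[i] if rng.uniform() < 0.8 else "normal")
                      for i in cases}

        def fit_predict(train_cases, train_labels, test_cases):
            return [fixed_pred[i] for i in test_cases]

        df = kfold_evaluate(cases, labels, k=8, seed=2, fit_predict=fit_predict)
        plain = 100.0 * np.mean([fixed_pred[i] == labels[i] for i in cases])
        mean_row = df[df["fold"] == "mean"].iloc[0]
        assert mean_row["accuracy"] == pytest.approx(plain, abs=1e-9)


class TestPearson:
    def test_perfect_positive(self):
        x = np.arange(10.0)
        assert pearson_r(x, x) == pytest.approx(1.0)

    def test_perfect_negative_affine(self):
        x = np.arange(10.0)
        assert pearson_r(x, -2 * x + 5) == pytest.approx(-1.0)

    def test_small_example_against_direct_formula_and_scipy(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        y = np.array([2.0, 1.0, 4.0, 3.0])
        direct = np.sum((x - x.mean()) * (y - y.mean())) / (
            3 * x.std(ddof=1) * y.std(ddof=1)
        )
        assert pearson_r(x, y) == pytest.approx(0.6)
        assert pearson_r(x, y) == pytest.approx(direct)
        assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)

    @given(
        a=st.floats(0.1, 10), b=st.floats(-5, 5),
        seed=st.integers(0, 100),
    )
    def test_invariant_under_positive_affine_maps(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x = rng.normal(size=12)
        y = rng.normal(size=12) + 0.5 * x
        r0 = pearson_r(x, y)
        assert pearson_r(a * x + b, y) == pytest.approx(r0, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(UndefinedMetricError):
            pearson_r(np.ones(5), np.arange(5.0))


class TestBlandAltman:
    def test_identical_vectors(self):
        x = np.array([1.0, 2.0, 3.0])
        s = bland_altman(x, x)
        assert s.mean_diff == 0.0
        assert s.lower_limit == s.upper_limit == 0.0

    def test_constant_offset(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        s = bland_altman(x + 2.5, x)
        assert s.mean_diff == pytest.approx(2.5)
        assert s.sd_diff == pytest.approx(0.0)
        assert s.lower_limit == s.upper_limit == pytest.approx(2.5)

    def test_limits_bracket_most_differences(self):
        rng = np.random.default_rng(3)
        a = rng.normal(50, 5, size=500)
        b = a + rng.normal(0.5, 1.0, size=500)
        s = bland_altman(a, b)
        diff = a - b
        coverage = np.mean((diff >= s.lower_limit) & (diff <= s.upper_limit))
        assert coverage >= 0.93
        assert len(s.table) == 500

    def test_length_mismatch(self):
        with pytest.raises(Kerato3dError):
            bland_altman(np.ones(4), np.ones(5))
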