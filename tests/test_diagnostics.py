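"""Confusion matrices, metrics, ROC/AUC, cut-off selection, summaries and
the confusion-matrix reconstruction oracle."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import kscem
from kscem.diagnostics import (
    ConfusionMatrix,
    DegenerateCutoffWarning,
    auc,
    clinical_cutoff_100npv,
    confusion_at_cutoff,
    evaluate_scores,
    metrics,
    reconstruct_confusion,
    roc_points,
    summarize_scores,
    youden_optimal_cutoff,
)


def pairwise_auc(scores, labels):
    """Independent oracle: literal average over all (malignant, benign)
    pairs with half credit for ties."""
    pos = [s for s, l in zip(scores, labels) if l == "malignant"]
    neg = [s for s, l in zip(scores, labels) if l == "benign"]
    total = 0.0
    for p in pos:
        for n in neg:
            total += 1.0 if p > n else (0.5 if p == n else 0.0)
    return total / (len(pos) * len(neg))


@st.composite
def two_class_instance(draw):
    m = draw(st.integers(min_value=1, max_value=10))
    n = draw(st.integers(min_value=1, max_value=10))
    scores = draw(st.lists(st.integers(1, 12), min_size=m + n, max_size=m + n))
    labels = ["malignant"] * m + ["benign"] * n
    return scores, labels


class TestConfusion:
    def test_tiny_example(self):
        cm = confusion_at_cutoff([1, 9], ["benign", "malignant"], 5)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 0, 0, 1)

    def test_fixture_at_cutoff_six(self, mri_scores_labels):
        scores, labels = mri_scores_labels
        cm = confusion_at_cutoff(scores, labels, 6)
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (42, 1, 5, 20)

    def test_cutoff_below_minimum_calls_everything_positive(self, mri_scores_labels):
        cm = confusion_at_cutoff(*mri_scores_labels, 1)
        assert cm.fn == 0 and cm.tn == 0

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([1, 2], ["benign", "benign"], 1)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            confusion_at_cutoff([1, 2, 3], ["benign", "malignant"], 1)

    def test_unknown_label_rejected(self):
        with pytest.raises(ValueError, match="equivocal"):
            confusion_at_cutoff([1, 2], ["benign", "equivocal"], 1)

    @given(two_class_instance(), st.integers(1, 13))
    def test_margins_conserved_across_cutoffs(self, inst, cutoff):
        scores, labels = inst
        cm = confusion_at_cutoff(scores, labels, cutoff)
        assert cm.tp + cm.fn == labels.count("malignant")
        assert cm.fp + cm.tn == labels.count("benign")


class TestMetrics:
    def test_fixture_youden_point_arithmetic(self):
        m = metrics(ConfusionMatrix(tp=42, fp=1, fn=5, tn=20))
        assert m.sensitivity == pytest.approx(42 / 47)
        assert m.specificity == pytest.approx(20 / 21)
        assert m.ppv == pytest.approx(42 / 43)
        assert m.npv == pytest.approx(20 / 25)
        assert m.youden_j == pytest.approx(42 / 47 + 20 / 21 - 1)
        assert not m.undefined

    def test_zero_denominators_flagged_not_zeroed(self):
        m = metrics(ConfusionMatrix(tp=0, fp=3, fn=0, tn=2))
        assert math.isnan(m.sensitivity)
        assert {"sensitivity", "youden_j"} <= m.undefined

    def test_perfect_matrix(self):
        m = metrics(ConfusionMatrix(tp=5, fp=0, fn=0, tn=5))
        assert (m.sensitivity, m.specificity, m.ppv, m.npv, m.accuracy) == (1, 1, 1, 1, 1)
        assert m.youden_j == 1

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            ConfusionMatrix(tp=-1, fp=0, fn=0, tn=1)


class TestRocAndAuc:
    def test_perfect_separation(self):
        scores = [9, 9, 1, 1]
        labels = ["malignant", "malignant", "benign", "benign"]
        pts = roc_points(scores, labels)
        assert [0.0, 1.0] in pts.tolist()
        assert auc(scores, labels) == 1.0

    def test_identical_distributions(self):
        scores = [5, 5, 5, 5]
        labels = ["malignant", "malignant", "benign", "benign"]
        assert roc_points(scores, labels).tolist() == [[0, 0], [1, 1]]
        assert auc(scores, labels) == 0.5

    def test_staircase_is_monotone(self, mri_scores_labels):
        pts = roc_points(*mri_scores_labels)
        assert (np.diff(pts, axis=0) >= 0).all()
        assert pts[0].tolist() == [0, 0] and pts[-1].tolist() == [1, 1]

    @given(two_class_instance())
    def test_pair_counting_equals_trapezoidal_area(self, inst):
        scores, labels = inst
        pts = roc_points(scores, labels)
        area = float(np.trapezoid(pts[:, 1], pts[:, 0]))
        assert auc(scores, labels) == pytest.approx(area, abs=1e-12)

    @given(two_class_instance())
    def test_auc_matches_exhaustive_pair_oracle(self, inst):
        scores, labels = inst
        assert auc(scores, labels) == pytest.approx(pairwise_auc(scores, labels), abs=1e-12)

    def test_auc_matches_sklearn(self, mri_scores_labels):
        from sklearn.metrics import roc_auc_score

        scores, labels = mri_scores_labels
        expected = roc_auc_score([l == "malignant" for l in labels], scores)
        assert auc(scores, labels) == pytest.approx(expected, abs=1e-12)


class TestCutoffSelection:
    def test_fixture_youden_cutoffs(self, mri_scores_labels, cem_scores_labels):
        assert youden_optimal_cutoff(*mri_scores_labels) == 6
        assert youden_optimal_cutoff(*cem_scores_labels) == 6

    def test_tie_break_on_separated_pair(self):
        # any cut-off in (1, 9] separates perfectly; the candidate grid is
        # the distinct scores, so the band is entered at 9
        assert youden_optimal_cutoff([1, 9], ["benign", "malignant"]) == 9

    @given(two_class_instance())
    def test_agrees_with_brute_force_over_integer_grid(self, inst):
        scores, labels = inst
        best = youden_optimal_cutoff(scores, labels)
        js = {}
        for c in range(1, 14):
            m = metrics(confusion_at_cutoff(scores, labels, c))
            js[c] = m.youden_j
        assert js[best] == pytest.approx(max(js.values()), abs=1e-12)

    def test_fixture_clinical_cutoff(self, mri_scores_labels, cem_scores_labels):
        assert clinical_cutoff_100npv(*mri_scores_labels) == 3
        assert clinical_cutoff_100npv(*cem_scores_labels) == 3

    def test_clinical_cutoff_is_minimum_malignant_score(self):
        scores = [2, 4, 7, 1, 1, 3]
        labels = ["malignant"] * 3 + ["benign"] * 3
        c = clinical_cutoff_100npv(scores, labels)
        assert c == 2
        assert confusion_at_cutoff(scores, labels, c).fn == 0

    def test_degenerate_when_no_benign_scores_below(self):
        scores = [3, 4, 5, 6]
        labels = ["malignant", "malignant", "benign", "benign"]
        with pytest.warns(DegenerateCutoffWarning):
            assert clinical_cutoff_100npv(scores, labels) == 3


class TestSummaries:
    def test_fixture_group_summaries(self, fixture_spec):
        s = summarize_scores(fixture_spec.scores("malignant", "mri"))
        assert (s.median, s.iqr_low, s.iqr_high) == (9, 8, 9)
        s = summarize_scores(fixture_spec.scores("benign", "mri"))
        assert (s.median, s.iqr_low, s.iqr_high) == (3, 2, 3)

    def test_single_value(self):
        s = summarize_scores([7])
        assert (s.median, s.iqr_low, s.iqr_high) == (7, 7, 7)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            summarize_scores([])

    @given(st.lists(st.integers(1, 12), min_size=1, max_size=30))
    def test_quartiles_bracket_median(self, values):
        s = summarize_scores(values)
        assert s.iqr_low <= s.median <= s.iqr_high


class TestReconstruction:
    def test_mri_youden_row_is_unique(self):
        res = reconstruct_confusion(47, 21, [("ppv", "97.67", 2), ("npv", "80", 0)])
        assert res.unique
        cm = res.matrices[0]
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (42, 1, 5, 20)
        # the surviving matrix reproduces the remaining printed cells
        m = metrics(cm)
        assert round(100 * m.sensitivity, 2) == 89.36
        assert round(100 * m.specificity, 2) == 95.24

    def test_cem_youden_row_is_unique(self):
        res = reconstruct_confusion(47, 21, [("ppv", "97.62", 2), ("npv", "76.92", 2)])
        assert res.unique
        cm = res.matrices[0]
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (41, 1, 6, 20)
        m = metrics(cm)
        assert round(100 * m.sensitivity, 2) == 87.23
        assert round(100 * m.specificity, 2) == 95.24

    def test_100npv_row_is_unique(self):
        res = reconstruct_confusion(47, 21, [("npv", "100", 0), ("ppv", "75.81", 2)])
        assert res.unique
        assert (res.matrices[0].tp, res.matrices[0].fp) == (47, 15)

    def test_trivial_perfect_row(self):
        res = reconstruct_confusion(10, 10, [("sensitivity", "100", 0), ("specificity", "100", 0)])
        assert res.unique
        assert (res.matrices[0].tp, res.matrices[0].tn) == (10, 10)

    def test_inconsistent_constraints_reported_not_raised(self):
        res = reconstruct_confusion(
            47, 21, [("ppv", "97.67", 2), ("npv", "80", 0), ("accuracy", "88.2", 1)]
        )
        assert not res.consistent
        assert res.matrices == ()

    def test_published_accuracy_cells_are_inconsistent(self):
        # the uniquely reconstructed operating points give different accuracy
        mri = reconstruct_confusion(47, 21, [("ppv", "97.67", 2), ("npv", "80", 0)]).matrices[0]
        cem = reconstruct_confusion(47, 21, [("ppv", "97.62", 2), ("npv", "76.92", 2)]).matrices[0]
        assert round(100 * metrics(mri).accuracy, 1) == 91.2 != 88.2
        assert round(100 * metrics(cem).accuracy, 1) == 89.7 != 86.8

    def test_bad_inputs_rejected(self):
        with pytest.raises(ValueError):
            reconstruct_confusion(0, 5, [("ppv", "50", 0)])
        with pytest.raises(ValueError):
            reconstruct_confusion(5, 5, [])
        with pytest.raises(ValueError):
            reconstruct_confusion(5, 5, [("f1", "50", 0)])


class TestEvaluateScores:
    def test_fixture_summary_object(self, mri_scores_labels):
        s = evaluate_scores(*mri_scores_labels)
        assert s.youden_cutoff == 6
        assert s.clinical_cutoff_100npv == 3
        assert s.auc == pytest.approx(938.5 / 987, abs=1e-12)
        assert s.metrics_at_clinical.npv == 1.0
        assert (s.cm_at_youden.tp, s.cm_at_youden.tn) == (42, 20)
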