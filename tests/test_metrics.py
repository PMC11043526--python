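import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

import enumstack as es
from .conftest import random_prediction
from .oracles import (
    ovr_metrics_from_confusion,
    tally_confusion,
    threshold_sweep_ap,
    u_statistic_auc,
)


def perfect_prediction(cohort):
    classes = cohort.class_names
    probs = pd.DataFrame(0.0, index=cohort.matrix.index, columns=classes)
    for sid, lab in cohort.labels.items():
        probs.loc[sid, lab] = 1.0
    return es.ProbabilityPrediction(classes, probs)


class TestConfusion:
    def test_perfect_predictions_are_diagonal(self, fixture_cohort):
        cm = es.confusion(fixture_cohort.labels, perfect_prediction(fixture_cohort))
        assert np.array_equal(cm.counts, np.diag([4, 4, 4]))

    def test_all_predicted_first_class_fills_first_column(self, fixture_cohort):
        probs = pd.DataFrame(
            [[1.0, 0.0, 0.0]] * 12, index=fixture_cohort.matrix.index, columns=("A", "B", "C")
        )
        cm = es.confusion(fixture_cohort.labels, es.ProbabilityPrediction(("A", "B", "C"), probs))
        assert np.array_equal(cm.counts, np.array([[4, 0, 0], [4, 0, 0], [4, 0, 0]]))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_sample_tally_oracle(self, seed):
        labels, pred = random_prediction(30, seed=seed)
        cm = es.confusion(labels, pred)
        oracle = tally_confusion(labels, pred.predicted_label, pred.classes)
        assert np.array_equal(cm.counts, oracle)
        assert cm.total == 30

    def test_unknown_class_raises(self, fixture_cohort):
        pred = perfect_prediction(fixture_cohort)
        bad = fixture_cohort.labels.copy()
        bad.iloc[0] = "D"
        with pytest.raises(ValueError, match="D"):
            es.confusion(bad, pred)


class TestMetricReport:
    def test_perfect_classifier_scores_one_everywhere(self, fixture_cohort):
        report = es.metric_report(fixture_cohort.labels, perfect_prediction(fixture_cohort))
        values = report.as_dict()
        assert len(values) == 11 and set(values) == set(es.METRIC_NAMES)
        assert all(v == 1.0 for v in values.values())

    def test_uniform_probabilities_resolve_to_first_class(self, fixture_cohort):
        probs = pd.DataFrame(
            np.full((12, 3), 1 / 3), index=fixture_cohort.matrix.index, columns=("A", "B", "C")
        )
        pred = es.ProbabilityPrediction(("A", "B", "C"), probs)
        assert set(pred.predicted_label) == {"A"}
        report = es.metric_report(fixture_cohort.labels, pred)
        oracle = ovr_metrics_from_confusion(
            tally_confusion(fixture_cohort.labels, pred.predicted_label, pred.classes),
            pred.classes,
        )
        assert report.balanced_accuracy == pytest.approx(1 / 3, abs=1e-12)
        assert report.balanced_accuracy == pytest.approx(oracle["sensitivity"], abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 3, 7, 11])
    def test_agrees_with_formula_oracles(self, seed):
        labels, pred = random_prediction(40, seed=seed)
        report = es.metric_report(labels, pred)
        counts = tally_confusion(labels, pred.predicted_label, pred.classes)
        oracle = ovr_metrics_from_confusion(counts, pred.classes)
        for name, expected in oracle.items():
            assert getattr(report, name) == pytest.approx(expected, abs=1e-9), name
        assert report.precision == report.ppv
        assert report.recall == report.sensitivity
        assert report.balanced_accuracy == report.sensitivity
        roc_oracle = np.mean(
            [
                u_statistic_auc((np.asarray(labels) == c).astype(int), pred.probs[c])
                for c in pred.classes
            ]
        )
        assert report.roc_auc == pytest.approx(roc_oracle, abs=1e-9)
        ap_oracle = np.mean(
            [
                threshold_sweep_ap((np.asarray(labels) == c).astype(int), pred.probs[c])
                for c in pred.classes
            ]
        )
        assert report.pr_auc == pytest.approx(ap_oracle, abs=1e-9)

    @given(seed=st.integers(0, 50))
    def test_all_metrics_within_unit_interval(self, seed):
        labels, pred = random_prediction(21, seed=seed)
        report = es.metric_report(labels, pred)
        assert all(0.0 <= v <= 1.0 for v in report.as_dict().values())

    def test_invariant_to_sample_order(self):
        labels, pred = random_prediction(30, seed=5)
        perm = np.random.default_rng(1).permutation(30)
        shuffled = es.ProbabilityPrediction(pred.classes, pred.probs.iloc[perm])
        assert es.metric_report(labels, pred) == es.metric_report(labels.iloc[perm], shuffled)

    def test_single_class_labels_rejected(self, fixture_cohort):
        pred = perfect_prediction(fixture_cohort)
        with pytest.raises(ValueError, match="2 classes"):
            es.metric_report(pd.Series(["A"] * 12, index=pred.probs.index), pred)


class TestAUCs:
    def test_perfect_ordering_gives_one(self):
        labels, pred = random_prediction(12, seed=0)
        assert es.macro_roc_auc(labels, perfect_probs(labels)) == 1.0
        assert es.macro_pr_auc(labels, perfect_probs(labels)) == 1.0

    def test_constant_scores_give_half_auc(self):
        labels, _ = random_prediction(12, seed=0)
        probs = pd.DataFrame(np.full((12, 3), 1 / 3), index=labels.index, columns=("A", "B", "C"))
        assert es.macro_roc_auc(labels, probs) == pytest.approx(0.5)

    def test_single_positive_ranked_last_has_ap_one_over_n(self):
        n = 8
        labels = pd.Series(["B"] * (n - 1) + ["A"], index=range(n))
        a_scores = np.linspace(0.9, 0.1, n)  # the lone A gets the lowest score
        probs = pd.DataFrame({"A": a_scores, "B": 1 - a_scores}, index=labels.index)
        per_class_a = threshold_sweep_ap((labels == "A").astype(int), probs["A"])
        assert per_class_a == pytest.approx(1 / n)

    def test_label_reversal_antisymmetry(self):
        rng = np.random.default_rng(2)
        y = rng.integers(0, 2, size=20)
        scores = rng.random(20)
        probs = pd.DataFrame({"neg": 1 - scores, "pos": scores})
        auc = u_statistic_auc(y, scores)
        auc_flipped = u_statistic_auc(1 - y, scores)
        assert auc_flipped == pytest.approx(1 - auc, abs=1e-12)
        labels = pd.Series(np.where(y, "pos", "neg"))
        assert es.macro_roc_auc(labels, probs) == pytest.approx(
            (auc + (1 - auc_flipped)) / 2, abs=1e-9
        )

    def test_degenerate_class_excluded_then_error(self):
        labels = pd.Series(["A", "A", "B", "B"])
        probs = pd.DataFrame(
            {"A": [0.8, 0.7, 0.2, 0.1], "B": [0.2, 0.3, 0.8, 0.9], "C": [0.0] * 4}
        )
        probs = probs.div(probs.sum(axis=1), axis=0)
        assert 0 <= es.macro_roc_auc(labels, probs) <= 1  # C silently excluded
        with pytest.raises(ValueError, match="degenerate"):
            es.macro_roc_auc(pd.Series(["A"] * 4), probs[["A"]].assign(A=1.0))


class TestMeanMetric:
    def make_report(self, value):
        return es.MetricReport(**{name: value for name in es.METRIC_NAMES})

    def test_identical_perfect_reports(self):
        assert es.mean_metric([self.make_report(1.0)] * 2) == 1.0

    def test_two_reports_average(self):
        assert es.mean_metric([self.make_report(0.8), self.make_report(0.6)]) == pytest.approx(0.7)

    @pytest.mark.parametrize("seed", [0, 1])
    def test_equals_flat_mean_of_all_values(self, seed):
        rng = np.random.default_rng(seed)
        reports = [
            es.MetricReport(**{name: rng.random() for name in es.METRIC_NAMES}) for _ in range(4)
        ]
        flat = np.mean([v for r in reports for v in r.as_dict().values()])
        assert es.mean_metric(reports) == pytest.approx(flat, abs=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            es.mean_metric([])


def perfect_probs(labels):
    classes = tuple(sorted(set(labels)))
    probs = pd.DataFrame(0.0, index=labels.index, columns=classes)
    for sid, lab in labels.items():
        probs.loc[sid, lab] = 1.0
    return probs
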