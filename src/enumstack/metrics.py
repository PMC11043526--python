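"""Multi-class evaluation: confusion matrices, the 11-metric report, and
macro-averaged ROC-AUC / PR-AUC.

All per-class quantities use the one-vs-rest framing and are macro-averaged
(unweighted mean over classes), so each subtype counts equally regardless of
prevalence. ``precision``/``recall`` are exact aliases of ``ppv``/
``sensitivity`` and are reported separately to keep the conventional
11-name metric list intact. Conventions that matter for reproducibility:

* argmax ties are broken in favour of the lexicographically first class name;
* a per-class metric with a zero denominator is defined as 0 (warning logged);
* a class absent from the true labels is dropped from macro averages
  (warning logged).
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd
from sklearn.metrics import average_precision_score, roc_auc_score

from .util import logger

__all__ = [
    "METRIC_NAMES",
    "ProbabilityPrediction",
    "ConfusionMatrix",
    "MetricReport",
    "confusion",
    "metric_report",
    "macro_roc_auc",
    "macro_pr_auc",
    "mean_metric",
    "balanced_accuracy",
]

METRIC_NAMES = (
    "accuracy",
    "balanced_accuracy",
    "f1",
    "npv",
    "ppv",
    "pr_auc",
    "precision",
    "recall",
    "roc_auc",
    "sensitivity",
    "specificity",
)


@dataclass
class ProbabilityPrediction:
    """Per-sample class-probability rows plus the implied argmax labels.

    ``classes`` is stored in lexicographic order and ``probs`` columns are
    re-ordered to match, so the argmax tie-break (first class name wins) is
    well defined.
    """

    classes: tuple[str, ...]
    probs: pd.DataFrame

    def __init__(self, classes, probs: pd.DataFrame):
        order = sorted(str(c) for c in classes)
        if sorted(probs.columns) != order:
            raise ValueError(
                f"probability columns {list(probs.columns)} do not match classes {order}"
            )
        self.classes = tuple(order)
        self.probs = probs.loc[:, order].astype(float)
        arr = self.probs.to_numpy()
        if (arr < -1e-9).any() or (arr > 1 + 1e-9).any():
            raise ValueError("probabilities outside [0, 1]")
        rowsum = arr.sum(axis=1)
        if np.abs(rowsum - 1.0).max() > 1e-6:
            bad = self.probs.index[int(np.argmax(np.abs(rowsum - 1.0)))]
            raise ValueError(f"probability row for sample {bad!r} does not sum to 1")

    @property
    def predicted_label(self) -> pd.Series:
        """Argmax class per row; ties go to the first (lexicographic) class."""
        idx = np.argmax(self.probs.to_numpy(), axis=1)
        return pd.Series(
            [self.classes[i] for i in idx], index=self.probs.index, name="predicted"
        )

    @property
    def sample_ids(self) -> tuple:
        return tuple(self.probs.index)


@dataclass(frozen=True)
class ConfusionMatrix:
    """K x K count table; rows are true classes, columns predicted classes."""

    classes: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self) -> None:
        k = len(self.classes)
        if self.counts.shape != (k, k) or (self.counts < 0).any():
            raise ValueError("counts must be a K x K non-negative table")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)


@dataclass(frozen=True)
class MetricReport:
    """The 11 named performance metrics of one model on one labelled set."""

    accuracy: float
    balanced_accuracy: float
    f1: float
    npv: float
    ppv: float
    pr_auc: float
    precision: float
    recall: float
    roc_auc: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def grand_mean(self) -> float:
        """Unweighted mean of the 11 metric values."""
        return float(np.mean(list(self.as_dict().values())))

    @staticmethod
    def mean(reports: list["MetricReport"]) -> "MetricReport":
        """Metric-wise mean across reports (e.g. across CV folds)."""
        if not reports:
            raise ValueError("cannot average an empty list of reports")
        return MetricReport(
            **{
                name: float(np.mean([r.as_dict()[name] for r in reports]))
                for name in METRIC_NAMES
            }
        )


def _check_classes(true_labels: pd.Series, classes: tuple[str, ...]) -> None:
    unknown = sorted(set(true_labels) - set(classes))
    if unknown:
        raise ValueError(f"true labels contain classes unknown to the prediction: {unknown}")


def confusion(true_labels: pd.Series, pred: ProbabilityPrediction) -> ConfusionMatrix:
    """Tally a confusion matrix from argmax labels of ``pred``."""
    true_labels = pd.Series(true_labels)
    if len(true_labels) != len(pred.probs):
        raise ValueError("true labels and predictions differ in sample count")
    _check_classes(true_labels, pred.classes)
    k = len(pred.classes)
    pos = {c: i for i, c in enumerate(pred.classes)}
    counts = np.zeros((k, k), dtype=int)
    for t, p in zip(true_labels, pred.predicted_label):
        counts[pos[t], pos[p]] += 1
    return ConfusionMatrix(pred.classes, counts)


def _safe_div(num: float, den: float, what: str) -> float:
    if den == 0:
        logger.warning("zero denominator for %s; defining the term as 0", what)
        return 0.0
    return num / den


def _per_class_rates(cm: ConfusionMatrix) -> dict[str, dict[str, float]]:
    """One-vs-rest sensitivity/specificity/ppv/npv/f1 per present class."""
    out: dict[str, dict[str, float]] = {}
    total = cm.total
    for i, c in enumerate(cm.classes):
        tp = cm.counts[i, i]
        fn = cm.counts[i, :].sum() - tp
        fp = cm.counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        if tp + fn == 0:
            logger.warning("class %s absent from true labels; excluded from macro average", c)
            continue
        sens = _safe_div(tp, tp + fn, f"sensitivity[{c}]")
        spec = _safe_div(tn, tn + fp, f"specificity[{c}]")
        ppv = _safe_div(tp, tp + fp, f"ppv[{c}]")
        npv = _safe_div(tn, tn + fn, f"npv[{c}]")
        f1 = _safe_div(2 * ppv * sens, ppv + sens, f"f1[{c}]")
        out[c] = {"sensitivity": sens, "specificity": spec, "ppv": ppv, "npv": npv, "f1": f1}
    return out


def _per_class_auc(
    true_labels: pd.Series, probs: pd.DataFrame, score_fn, what: str
) -> float:
    """Macro mean of a one-vs-rest threshold-free score over non-degenerate classes."""
    vals = []
    for c in probs.columns:
        y = (np.asarray(true_labels) == c).astype(int)
        if y.sum() == 0 or y.sum() == len(y):
            logger.warning("class %s degenerate for %s; excluded from macro average", c, what)
            continue
        vals.append(score_fn(y, probs[c].to_numpy()))
    if not vals:
        raise ValueError(f"all classes degenerate; {what} undefined")
    return float(np.mean(vals))


def macro_roc_auc(true_labels: pd.Series, probs: pd.DataFrame) -> float:
    """Macro-averaged one-vs-rest ROC-AUC (rank statistic; ties count 0.5)."""
    return _per_class_auc(true_labels, probs, roc_auc_score, "roc_auc")


def macro_pr_auc(true_labels: pd.Series, probs: pd.DataFrame) -> float:
    """Macro-averaged one-vs-rest average precision (step-wise PR summation)."""
    return _per_class_auc(true_labels, probs, average_precision_score, "pr_auc")


def metric_report(true_labels: pd.Series, pred: ProbabilityPrediction) -> MetricReport:
    """Compute the 11-metric report for one prediction on one labelled set."""
    true_labels = pd.Series(true_labels)
    present = set(true_labels)
    if len(present) < 2:
        raise ValueError("metric report requires >= 2 classes present in true labels")
    cm = confusion(true_labels, pred)
    rates = _per_class_rates(cm)
    macro = {
        name: float(np.mean([r[name] for r in rates.values()]))
        for name in ("sensitivity", "specificity", "ppv", "npv", "f1")
    }
    acc = _safe_div(float(np.trace(cm.counts)), cm.total, "accuracy")
    return MetricReport(
        accuracy=acc,
        balanced_accuracy=macro["sensitivity"],
        f1=macro["f1"],
        npv=macro["npv"],
        ppv=macro["ppv"],
        pr_auc=macro_pr_auc(true_labels, pred.probs),
        precision=macro["ppv"],
        recall=macro["sensitivity"],
        roc_auc=macro_roc_auc(true_labels, pred.probs),
        sensitivity=macro["sensitivity"],
        specificity=macro["specificity"],
    )


def balanced_accuracy(true_labels: pd.Series, predicted_labels: pd.Series) -> float:
    """Mean per-class recall over classes present in the true labels.

    Cheap label-only path used as the hyperparameter-tuning objective.
    """
    t = np.asarray(pd.Series(true_labels))
    p = np.asarray(pd.Series(predicted_labels))
    recalls = [np.mean(p[t == c] == c) for c in sorted(set(t))]
    return float(np.mean(recalls))


def mean_metric(reports: list[MetricReport]) -> float:
    """Grand mean of all 11 metrics across reports — the catalogue rank score."""
    if not reports:
        raise ValueError("mean_metric of an empty report list")
    return float(np.mean([r.grand_mean() for r in reports]))
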