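"""Gene-set reduction by SVM-RFE and random-forest backward elimination.

Two complementary selectors, combined by union (default) or intersection:

* **SVM-RFE** — recursive feature elimination driven by a linear SVM. At
  each round a one-vs-rest linear SVM is fitted and each feature is scored
  by the sum over class weight vectors of its squared coefficient; the
  lowest-scoring features are dropped until the target size is reached.
  Because the SVM is refitted after every drop, the criterion accounts for
  interactions among the surviving features.
* **RF backward elimination** (varSelRF-style) — a random forest is fitted
  once and features ranked by permutation importance; then the bottom
  fraction (default 20%) is dropped round by round, refitting and recording
  the out-of-bag error at each size, down to 2 features. The selected set is
  the smallest one whose OOB error is within ``sd_tolerance`` binomial
  standard errors of the minimum (the 1-SE rule). Importances are computed
  once, on the full model, to avoid the selection bias of re-ranking inside
  the elimination loop.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.svm import LinearSVC

from .synthetic import LabeledCohort
from .util import logger

__all__ = [
    "RFESchedule",
    "SelectionResult",
    "svm_rfe",
    "rf_backward",
    "combine_selections",
]


@dataclass(frozen=True)
class RFESchedule:
    """Per-round removal size (count, or fraction of remaining) and stop size."""

    step: float = 1
    target_size: int = 1

    def __post_init__(self):
        if self.step <= 0:
            raise ValueError("step must be positive")
        if self.target_size < 1:
            raise ValueError("target_size must be >= 1")

    def n_remove(self, current: int) -> int:
        raw = self.step if self.step >= 1 else self.step * current
        n = max(1, int(np.floor(raw + 0.5)))
        return min(n, current - self.target_size)


@dataclass
class SelectionResult:
    method: str  # svm_rfe | rf_backward | combined
    selected: tuple[str, ...]
    trajectory: list[tuple[int, float]] = field(default_factory=list)

    def __post_init__(self):
        if not self.selected:
            raise ValueError("selection result must be non-empty")


def svm_rfe(
    cohort: LabeledCohort, schedule: RFESchedule, seed: int = 0
) -> SelectionResult:
    """Recursive feature elimination by squared linear-SVM weights."""
    x = cohort.matrix
    if x.shape[1] < 2:
        raise ValueError("svm_rfe needs at least 2 features")
    if not all(np.issubdtype(dt, np.number) for dt in x.dtypes):
        raise ValueError("svm_rfe requires an all-numeric matrix")
    y = np.asarray(cohort.labels)
    surviving = list(x.columns)
    trajectory: list[tuple[int, float]] = []
    while len(surviving) > schedule.target_size:
        svm = LinearSVC(C=1.0, dual="auto", max_iter=10000, random_state=seed)
        svm.fit(x[surviving].to_numpy(), y)
        coef = np.atleast_2d(svm.coef_)
        scores = (coef**2).sum(axis=0)  # summed over one-vs-rest class vectors
        trajectory.append((len(surviving), float(svm.score(x[surviving].to_numpy(), y))))
        order = np.argsort(scores, kind="stable")  # ascending: weakest first
        drop = {surviving[i] for i in order[: schedule.n_remove(len(surviving))]}
        surviving = [f for f in surviving if f not in drop]
    trajectory.append((len(surviving), float("nan")))
    return SelectionResult("svm_rfe", tuple(surviving), trajectory)


def backward_sizes(start: int, drop_fraction: float) -> list[int]:
    """Visited set sizes when dropping max(1, round(fraction * current)) per round."""
    sizes = [start]
    while sizes[-1] > 2:
        cur = sizes[-1]
        sizes.append(cur - max(1, int(np.floor(drop_fraction * cur + 0.5))))
    if sizes[-1] < 2:
        sizes[-1] = 2
    return sizes


def rf_backward(
    cohort: LabeledCohort,
    drop_fraction: float = 0.2,
    sd_tolerance: float = 1.0,
    seed: int = 0,
    n_estimators: int = 300,
) -> SelectionResult:
    """varSelRF-style backward elimination on out-of-bag error."""
    x = cohort.matrix
    if x.shape[1] < 2:
        raise ValueError("rf_backward needs at least 2 features")
    y = np.asarray(cohort.labels)
    if len(set(y)) < 2:
        raise ValueError("rf_backward needs at least 2 classes")

    def fit_rf(cols: list[str]) -> RandomForestClassifier:
        rf = RandomForestClassifier(
            n_estimators=n_estimators, oob_score=True, random_state=seed, n_jobs=1
        )
        rf.fit(x[cols].to_numpy(), y)
        return rf

    full_cols = list(x.columns)
    full_rf = fit_rf(full_cols)
    imp = permutation_importance(
        full_rf, x.to_numpy(), y, n_repeats=5, random_state=seed, n_jobs=1
    ).importances_mean
    ranking = [full_cols[i] for i in np.argsort(-imp, kind="stable")]  # best first

    n = len(y)
    trajectory: list[tuple[int, float]] = []
    sets: dict[int, tuple[str, ...]] = {}
    for size in backward_sizes(len(full_cols), drop_fraction):
        cols = ranking[:size]
        rf = full_rf if size == len(full_cols) else fit_rf(cols)
        oob_err = 1.0 - float(rf.oob_score_)
        trajectory.append((size, oob_err))
        sets[size] = tuple(cols)

    errs = dict(trajectory)
    min_err = min(errs.values())
    se = float(np.sqrt(max(min_err * (1 - min_err), 1e-12) / n))
    threshold = min_err + sd_tolerance * se
    chosen_size = min(s for s, e in errs.items() if e <= threshold)
    logger.info(
        "rf_backward: min OOB error %.4f, threshold %.4f, selected %d features",
        min_err,
        threshold,
        chosen_size,
    )
    return SelectionResult("rf_backward", sets[chosen_size], trajectory)


def combine_selections(
    a: SelectionResult, b: SelectionResult, mode: str = "union"
) -> SelectionResult:
    """Pool two selections by set union (default) or intersection."""
    sa, sb = set(a.selected), set(b.selected)
    if mode == "union":
        combined = sa | sb
    elif mode == "intersection":
        combined = sa & sb
        if not combined:
            raise ValueError(
                "intersection of the two selections is empty; rerun with mode='union'"
            )
    else:
        raise ValueError(f"unknown combination mode {mode!r}")
    return SelectionResult("combined", tuple(sorted(combined)), [])
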