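"""Registry of the nine first-layer (base) learning algorithms.

The nine algorithms — multinomial logistic regression, decision tree, random
forest, XGBoost, multilayer perceptron, elastic net, SVM, LightGBM and
K-nearest neighbours — are wrapped behind a uniform probability-emitting
interface: every backend is fitted on integer-encoded labels (sorted class
names) and returns a samples x K probability DataFrame with lexicographically
ordered class columns. SVM probabilities come from the backend's built-in
Platt calibration. All backends run single-threaded and seeded so catalogue
runs are reproducible.

Default hyperparameter search spaces are package choices (the common ranges
used for tabular expression data of a few hundred samples) and can be
overridden per run. ``compact_search_spaces`` narrows the ensemble-size and
network-width ranges for quick small-cohort runs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from lightgbm import LGBMClassifier
from sklearn.ensemble import RandomForestClassifier
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC
from sklearn.tree import DecisionTreeClassifier
from xgboost import XGBClassifier

from .metrics import MetricReport, ProbabilityPrediction, metric_report
from .synthetic import LabeledCohort
from .tuning import (
    Integer,
    Real,
    SearchSpace,
    TuneProtocol,
    TuneResult,
    cv_objective,
    make_folds,
    tune,
)
from .util import derive_seed, logger

__all__ = [
    "ALGORITHM_IDS",
    "DISPLAY_NAMES",
    "default_space",
    "compact_search_spaces",
    "make_estimator",
    "TunedModel",
    "fit_base",
    "oof_probabilities",
    "select_top_base",
]

ALGORITHM_IDS = (
    "decision_tree",
    "elastic_net",
    "knn",
    "lightgbm",
    "logistic_multinomial",
    "mlp",
    "random_forest",
    "svm",
    "xgboost",
)

#: Human-facing short names used in stacked-model names.
DISPLAY_NAMES = {
    "logistic_multinomial": "LR",
    "decision_tree": "DT",
    "random_forest": "RF",
    "xgboost": "XGBoost",
    "mlp": "MLP",
    "elastic_net": "Enet",
    "svm": "SVM",
    "lightgbm": "LightGBM",
    "knn": "KNN",
}
ID_FROM_DISPLAY = {v: k for k, v in DISPLAY_NAMES.items()}

_DEFAULT_SPACES: dict[str, dict] = {
    "logistic_multinomial": {"C": Real(1e-2, 1e2, log=True)},
    "decision_tree": {"max_depth": Integer(2, 12)},
    "random_forest": {
        "n_estimators": Integer(100, 1000),
        "max_features": Real(0.1, 1.0),
    },
    "xgboost": {
        "max_depth": Integer(2, 8),
        "learning_rate": Real(1e-3, 0.3, log=True),
        "n_estimators": Integer(50, 500),
    },
    "mlp": {"hidden_units": Integer(8, 128), "alpha": Real(1e-5, 1e-1, log=True)},
    "elastic_net": {"l1_ratio": Real(0.0, 1.0), "lam": Real(1e-4, 10.0, log=True)},
    "svm": {"C": Real(1e-2, 1e2, log=True), "gamma": Real(1e-4, 1.0, log=True)},
    "lightgbm": {
        "max_depth": Integer(2, 8),
        "learning_rate": Real(1e-3, 0.3, log=True),
        "n_estimators": Integer(50, 500),
    },
    "knn": {"n_neighbors": Integer(3, 25)},
}


def default_space(algorithm_id: str) -> SearchSpace:
    if algorithm_id not in _DEFAULT_SPACES:
        raise KeyError(f"unknown algorithm {algorithm_id!r}; known: {sorted(ALGORITHM_IDS)}")
    return SearchSpace(dict(_DEFAULT_SPACES[algorithm_id]))


def compact_search_spaces() -> dict[str, SearchSpace]:
    """Narrow spaces (small ensembles / narrow networks) for small cohorts."""
    compact = {k: dict(v) for k, v in _DEFAULT_SPACES.items()}
    compact["random_forest"]["n_estimators"] = Integer(50, 150)
    compact["xgboost"]["n_estimators"] = Integer(30, 100)
    compact["lightgbm"]["n_estimators"] = Integer(30, 100)
    compact["mlp"]["hidden_units"] = Integer(8, 32)
    return {k: SearchSpace(v) for k, v in compact.items()}


class _Backend:
    """Uniform fit/predict-probability wrapper over the nine library backends.

    Labels are integer-encoded against the sorted class names at fit time so
    every backend (including XGBoost, which requires numeric targets) sees
    the same encoding, and probability columns always come back in
    lexicographic class order.
    """

    def __init__(self, algorithm_id: str, params: dict, seed: int):
        self.algorithm_id = algorithm_id
        self.params = dict(params)
        self.seed = seed
        self.classes_: tuple[str, ...] = ()
        self._est = None

    def _build(self, n_samples: int):
        p, seed = self.params, self.seed
        if self.algorithm_id == "logistic_multinomial":
            return LogisticRegression(C=p.get("C", 1.0), max_iter=2000)
        if self.algorithm_id == "decision_tree":
            return DecisionTreeClassifier(max_depth=p.get("max_depth"), random_state=seed)
        if self.algorithm_id == "random_forest":
            return RandomForestClassifier(
                n_estimators=int(p.get("n_estimators", 500)),
                max_features=p.get("max_features", "sqrt"),
                random_state=seed,
                n_jobs=1,
            )
        if self.algorithm_id == "xgboost":
            return XGBClassifier(
                max_depth=int(p.get("max_depth", 4)),
                learning_rate=p.get("learning_rate", 0.1),
                n_estimators=int(p.get("n_estimators", 200)),
                tree_method="hist",
                verbosity=0,
                n_jobs=1,
                random_state=seed,
            )
        if self.algorithm_id == "mlp":
            return MLPClassifier(
                hidden_layer_sizes=(int(p.get("hidden_units", 32)),),
                alpha=p.get("alpha", 1e-4),
                max_iter=400,
                random_state=seed,
            )
        if self.algorithm_id == "elastic_net":
            return LogisticRegression(
                solver="saga",
                l1_ratio=p.get("l1_ratio", 0.5),
                C=1.0 / p.get("lam", 1.0),
                max_iter=3000,
            )
        if self.algorithm_id == "svm":
            return SVC(
                C=p.get("C", 1.0),
                gamma=p.get("gamma", "scale"),
                probability=True,
                random_state=seed,
            )
        if self.algorithm_id == "lightgbm":
            return LGBMClassifier(
                max_depth=int(p.get("max_depth", 4)),
                learning_rate=p.get("learning_rate", 0.1),
                n_estimators=int(p.get("n_estimators", 200)),
                min_child_samples=5,
                verbose=-1,
                n_jobs=1,
                random_state=seed,
            )
        if self.algorithm_id == "knn":
            # k is clamped so tiny training folds remain usable
            k = min(int(p.get("n_neighbors", 5)), max(1, n_samples - 1))
            return KNeighborsClassifier(n_neighbors=k)
        raise KeyError(f"unknown algorithm {self.algorithm_id!r}")

    def fit(self, x: pd.DataFrame, y) -> "_Backend":
        y = np.asarray(pd.Series(y), dtype=object)
        self.classes_ = tuple(sorted(set(y)))
        codes = np.array([self.classes_.index(v) for v in y])
        self._est = self._build(len(y))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", UserWarning)
            warnings.simplefilter("ignore", FutureWarning)
            self._est.fit(x.to_numpy(), codes)
        return self

    def predict_proba_frame(self, x: pd.DataFrame) -> pd.DataFrame:
        if self._est is None:
            raise RuntimeError("backend not fitted")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            raw = self._est.predict_proba(x.to_numpy())
        # backends report classes_ as the sorted integer codes they saw
        cols = [self.classes_[int(c)] for c in self._est.classes_]
        frame = pd.DataFrame(raw, index=x.index, columns=cols)
        missing = [c for c in self.classes_ if c not in frame.columns]
        for c in missing:  # pragma: no cover — only if a class vanished from a fold
            frame[c] = 0.0
        frame = frame.loc[:, list(self.classes_)]
        return frame.div(frame.sum(axis=1), axis=0)


def make_estimator(algorithm_id: str, params: dict, seed: int = 0) -> _Backend:
    if algorithm_id not in ALGORITHM_IDS:
        raise KeyError(f"unknown algorithm {algorithm_id!r}; known: {sorted(ALGORITHM_IDS)}")
    return _Backend(algorithm_id, params, seed)


@dataclass
class TunedModel:
    """A tuned, fitted learner bound to a fixed feature layout and class set."""

    algorithm_id: str
    hyperparameters: dict
    backend: _Backend
    feature_names: tuple[str, ...]
    class_names: tuple[str, ...]
    cv_report: MetricReport | None
    seed: int
    tune_result: TuneResult | None = None

    def predict(self, matrix: pd.DataFrame) -> ProbabilityPrediction:
        if tuple(matrix.columns) != self.feature_names:
            raise ValueError(
                f"{self.algorithm_id}: input features {list(matrix.columns)[:5]}... "
                f"do not match the training layout {list(self.feature_names)[:5]}..."
            )
        return ProbabilityPrediction(self.class_names, self.backend.predict_proba_frame(matrix))

    def grand_mean(self) -> float:
        if self.cv_report is None:
            raise ValueError(f"{self.algorithm_id}: no CV report available")
        return self.cv_report.grand_mean()


def fit_base(
    algorithm_id: str,
    cohort: LabeledCohort,
    protocol: TuneProtocol,
    space: SearchSpace | None = None,
) -> TunedModel:
    """Tune one base algorithm by CV, refit on the full cohort, report CV metrics.

    Hyperparameters are chosen by the SMBO loop with the mean-balanced-accuracy
    CV objective; the reported ``cv_report`` is the fold-wise mean of the full
    11-metric report at the chosen parameters; the deployed model is refitted
    on every training sample.
    """
    if algorithm_id not in ALGORITHM_IDS:
        raise KeyError(f"unknown algorithm {algorithm_id!r}; known: {sorted(ALGORITHM_IDS)}")
    space = space or default_space(algorithm_id)
    cv_seed = derive_seed(protocol.seed, "cv", algorithm_id)
    objective = cv_objective(algorithm_id, cohort, k=protocol.cv_folds, seed=cv_seed)
    result = tune(
        objective, space, replace(protocol, seed=derive_seed(protocol.seed, "tune", algorithm_id))
    )
    logger.info(
        "%s: best CV balanced accuracy %.3f after %d evaluations",
        algorithm_id,
        result.best_score,
        result.n_evaluations,
    )

    y = np.asarray(cohort.labels)
    fold_reports = []
    for tr, te in objective.folds:
        est = make_estimator(algorithm_id, result.best_params, seed=derive_seed(cv_seed, "cv-fit"))
        est.fit(cohort.matrix.iloc[tr], y[tr])
        pred = ProbabilityPrediction(
            est.classes_, est.predict_proba_frame(cohort.matrix.iloc[te])
        )
        fold_reports.append(metric_report(pd.Series(y[te]), pred))
    cv_report = MetricReport.mean(fold_reports)

    fit_seed = derive_seed(protocol.seed, "refit", algorithm_id)
    backend = make_estimator(algorithm_id, result.best_params, seed=fit_seed)
    backend.fit(cohort.matrix, y)
    return TunedModel(
        algorithm_id=algorithm_id,
        hyperparameters=result.best_params,
        backend=backend,
        feature_names=tuple(cohort.matrix.columns),
        class_names=backend.classes_,
        cv_report=cv_report,
        seed=fit_seed,
        tune_result=result,
    )


def oof_probabilities(
    algorithm_id: str,
    hyperparameters: dict,
    cohort: LabeledCohort,
    k: int = 5,
    seed: int = 0,
) -> ProbabilityPrediction:
    """Out-of-fold class probabilities for every training sample.

    Each sample's row comes from a model fitted with that sample's fold held
    out, so downstream meta-learners never see in-fold (leaky) probabilities.
    The fold plan matches :func:`enumstack.tuning.cv_objective` for the same
    ``(cohort, k, seed)``. The result carries ``fold_of`` (sample -> fold
    index) for leakage audits.
    """
    if k < 2:
        raise ValueError("out-of-fold generation requires k >= 2")
    y = np.asarray(cohort.labels)
    classes = tuple(sorted(set(y)))
    folds = make_folds(cohort, k, seed)
    probs = pd.DataFrame(
        np.zeros((len(y), len(classes))), index=cohort.matrix.index, columns=classes
    )
    fold_of = pd.Series(-1, index=cohort.matrix.index, dtype=int)
    for f, (tr, te) in enumerate(folds):
        est = make_estimator(algorithm_id, hyperparameters, seed=derive_seed(seed, "oof", f))
        est.fit(cohort.matrix.iloc[tr], y[tr])
        block = est.predict_proba_frame(cohort.matrix.iloc[te])
        block = block.reindex(columns=classes, fill_value=0.0)
        probs.iloc[te] = block.div(block.sum(axis=1), axis=0).to_numpy()
        fold_of.iloc[te] = f
    pred = ProbabilityPrediction(classes, probs)
    pred.fold_of = fold_of
    return pred


def select_top_base(models: list[TunedModel], k: int) -> list[TunedModel]:
    """Top-k models by the grand mean of their 11 CV metrics (ties: by id)."""
    if not models:
        raise ValueError("cannot select from an empty model list")
    if k > len(models):
        raise ValueError(f"k={k} exceeds the {len(models)} available models")
    ranked = sorted(models, key=lambda m: (-m.grand_mean(), m.algorithm_id))
    return ranked[:k]
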