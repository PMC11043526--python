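"""Sequential model-based (Bayesian) hyperparameter search.

The optimizer follows the classic SMBO loop: a random warm start of
``min(5, budget)`` points, then a Gaussian-process surrogate with an
expected-improvement acquisition maximized over a candidate pool. The search
contract mirrors the framework's tuning protocol: at most 50 evaluations by
default, early termination after 10 consecutive evaluations without a strict
improvement, balanced accuracy as the objective, and full determinism under a
fixed seed. Resampling plans (CV folds, bootstrap resamples) are frozen per
tuning run so every candidate parameter set is scored on identical data
splits — this keeps the objective comparable across iterations and makes
early stopping meaningful.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern
from sklearn.model_selection import KFold, StratifiedKFold

from .metrics import balanced_accuracy
from .util import derive_seed, logger

__all__ = [
    "Real",
    "Integer",
    "Categorical",
    "SearchSpace",
    "TuneProtocol",
    "TuneResult",
    "tune",
    "make_folds",
    "cv_objective",
    "bootstrap_objective",
]

# ---------------------------------------------------------------------------
# search-space dimensions


@dataclass(frozen=True)
class Real:
    low: float
    high: float
    log: bool = False

    def __post_init__(self):
        if not (math.isfinite(self.low) and math.isfinite(self.high)) or self.low >= self.high:
            raise ValueError("Real dimension needs finite low < high")
        if self.log and self.low <= 0:
            raise ValueError("log-scaled Real dimension needs low > 0")

    def sample(self, rng: np.random.Generator) -> float:
        if self.log:
            return float(np.exp(rng.uniform(np.log(self.low), np.log(self.high))))
        return float(rng.uniform(self.low, self.high))

    def encode(self, v: float) -> list[float]:
        if self.log:
            return [(math.log(v) - math.log(self.low)) / (math.log(self.high) - math.log(self.low))]
        return [(v - self.low) / (self.high - self.low)]


@dataclass(frozen=True)
class Integer:
    low: int
    high: int

    def __post_init__(self):
        if self.low > self.high:
            raise ValueError("Integer dimension needs low <= high")

    def sample(self, rng: np.random.Generator) -> int:
        return int(rng.integers(self.low, self.high + 1))

    def encode(self, v: int) -> list[float]:
        span = max(self.high - self.low, 1)
        return [(v - self.low) / span]

    @property
    def size(self) -> int:
        return self.high - self.low + 1


@dataclass(frozen=True)
class Categorical:
    choices: tuple

    def __post_init__(self):
        if not self.choices:
            raise ValueError("Categorical dimension needs a non-empty choice set")

    def sample(self, rng: np.random.Generator):
        return self.choices[int(rng.integers(len(self.choices)))]

    def encode(self, v) -> list[float]:
        return [1.0 if c == v else 0.0 for c in self.choices]

    @property
    def size(self) -> int:
        return len(self.choices)


Dimension = Real | Integer | Categorical


class SearchSpace:
    """Named hyperparameter dimensions over which the SMBO loop searches."""

    def __init__(self, dimensions: dict[str, Dimension]):
        if not dimensions:
            raise ValueError("search space must have at least one dimension")
        self.dimensions = dict(dimensions)

    def sample(self, rng: np.random.Generator) -> dict:
        return {name: dim.sample(rng) for name, dim in self.dimensions.items()}

    def encode(self, params: dict) -> np.ndarray:
        vec: list[float] = []
        for name, dim in self.dimensions.items():
            vec.extend(dim.encode(params[name]))
        return np.asarray(vec)

    def key(self, params: dict) -> tuple:
        return tuple(params[name] for name in self.dimensions)

    def grid(self, max_size: int = 1024) -> list[dict] | None:
        """Exhaustive grid if the space is fully discrete and small, else None."""
        axes = []
        for dim in self.dimensions.values():
            if isinstance(dim, Real):
                return None
            if isinstance(dim, Integer):
                axes.append(list(range(dim.low, dim.high + 1)))
            else:
                axes.append(list(dim.choices))
        size = math.prod(len(a) for a in axes)
        if size > max_size:
            return None
        names = list(self.dimensions)
        return [dict(zip(names, combo)) for combo in itertools.product(*axes)]


# ---------------------------------------------------------------------------
# protocol and result


@dataclass(frozen=True)
class TuneProtocol:
    """Budget and resampling settings of one tuning run."""

    max_iterations: int = 50
    early_stop_patience: int = 10
    objective: str = "balanced_accuracy"
    resampling: str = "kfold_cv"  # or "bootstrap"
    cv_folds: int = 5
    bootstrap_times: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.max_iterations < 1 or self.early_stop_patience < 1:
            raise ValueError("max_iterations and early_stop_patience must be >= 1")


@dataclass
class TuneResult:
    best_params: dict
    best_score: float
    history: list[tuple[dict, float]] = field(default_factory=list)

    @property
    def n_evaluations(self) -> int:
        return len(self.history)

    def history_frame(self) -> pd.DataFrame:
        import json

        return pd.DataFrame(
            {
                "iteration": range(1, len(self.history) + 1),
                "params": [json.dumps(p, default=str) for p, _ in self.history],
                "score": [s for _, s in self.history],
            }
        )


# ---------------------------------------------------------------------------
# the SMBO loop

_WARM_START = 5
_CANDIDATE_POOL = 96


def _expected_improvement(mu: np.ndarray, sigma: np.ndarray, best: float) -> np.ndarray:
    sigma = np.maximum(sigma, 1e-12)
    z = (mu - best) / sigma
    return (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)


def tune(
    objective_fn: Callable[[dict], float],
    space: SearchSpace,
    protocol: TuneProtocol,
) -> TuneResult:
    """Maximize ``objective_fn`` over ``space`` under the tuning protocol.

    Evaluations that raise are scored ``-inf`` (logged) and the search
    continues. Fully discrete spaces are never re-evaluated at the same
    point; if such a space is exhausted before the budget, the search stops.
    """
    rng = np.random.default_rng(protocol.seed)
    grid = space.grid()
    history: list[tuple[dict, float]] = []
    evaluated: set[tuple] = set()
    best_score = -np.inf
    best_params: dict | None = None
    stall = 0

    def evaluate(params: dict) -> None:
        nonlocal best_score, best_params, stall
        try:
            score = float(objective_fn(params))
        except Exception as exc:  # noqa: BLE001 — contract: score failures -inf
            logger.warning("objective failed at %s: %s", params, exc)
            score = -np.inf
        history.append((params, score))
        evaluated.add(space.key(params))
        if score > best_score:
            best_score, best_params, stall = score, params, 0
        else:
            stall += 1

    def propose_random() -> dict | None:
        for _ in range(200):
            params = space.sample(rng)
            if space.key(params) not in evaluated:
                return params
        return None if grid is not None else space.sample(rng)

    n_warm = min(_WARM_START, protocol.max_iterations)
    while len(history) < protocol.max_iterations and stall < protocol.early_stop_patience:
        if len(history) < n_warm:
            params = propose_random()
        else:
            params = _propose_by_surrogate(space, history, evaluated, grid, rng)
        if params is None:  # discrete space exhausted
            break
        evaluate(params)

    if best_params is None:
        raise RuntimeError("tuning failed: every objective evaluation raised")
    return TuneResult(best_params=best_params, best_score=best_score, history=history)


def _propose_by_surrogate(
    space: SearchSpace,
    history: list[tuple[dict, float]],
    evaluated: set[tuple],
    grid: list[dict] | None,
    rng: np.random.Generator,
) -> dict | None:
    finite = [s for _, s in history if np.isfinite(s)]
    floor = (min(finite) - 1.0) if finite else 0.0
    x = np.vstack([space.encode(p) for p, _ in history])
    y = np.asarray([s if np.isfinite(s) else floor for _, s in history])

    if grid is not None:
        candidates = [p for p in grid if space.key(p) not in evaluated]
        if not candidates:
            return None
    else:
        candidates = [space.sample(rng) for _ in range(_CANDIDATE_POOL)]
        candidates = [p for p in candidates if space.key(p) not in evaluated] or [
            space.sample(rng)
        ]

    kernel = ConstantKernel(1.0) * Matern(length_scale=np.full(x.shape[1], 0.5), nu=2.5)
    gp = GaussianProcessRegressor(
        kernel=kernel, alpha=1e-6, normalize_y=True, n_restarts_optimizer=0, random_state=0
    )
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # kernel-bound notices are routine here
            gp.fit(x, y)
            xc = np.vstack([space.encode(p) for p in candidates])
            mu, sigma = gp.predict(xc, return_std=True)
        ei = _expected_improvement(mu, sigma, y.max())
        return candidates[int(np.argmax(ei))]
    except Exception as exc:  # pragma: no cover — surrogate failure falls back to random
        logger.warning("surrogate fit failed (%s); falling back to a random proposal", exc)
        return candidates[int(rng.integers(len(candidates)))]


# ---------------------------------------------------------------------------
# objective builders


def make_folds(cohort, k: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    """K-fold split of a cohort, stratified when every class has >= k members.

    Drawn once per (cohort, k, seed); callers that must agree on folds (the
    CV objective and out-of-fold probability generation) pass the same seed.
    """
    y = np.asarray(cohort.labels)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        logger.warning(
            "classes %s have < %d members; using unstratified folds",
            list(counts[counts < k].index),
            k,
        )
        splitter = KFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
        return [(tr, te) for tr, te in splitter.split(cohort.matrix)]
    splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % (2**31))
    return [(tr, te) for tr, te in splitter.split(cohort.matrix, y)]


def cv_objective(learner_id: str, cohort, k: int = 5, seed: int = 0) -> Callable[[dict], float]:
    """Mean balanced accuracy over ``k`` stratified folds of the cohort.

    The fold assignment is drawn once (from ``seed``) and reused for every
    candidate parameter set. Classes with fewer than ``k`` members force a
    fall-back to unstratified folds (warning logged). The returned callable
    exposes the frozen folds as ``fn.folds`` for audit.
    """
    from .base_models import make_estimator  # local import; avoids a cycle

    y = np.asarray(cohort.labels)
    folds = make_folds(cohort, k, seed)

    def fn(params: dict) -> float:
        scores = []
        for tr, te in folds:
            est = make_estimator(learner_id, params, seed=derive_seed(seed, "cv-fit"))
            est.fit(cohort.matrix.iloc[tr], y[tr])
            pred = est.predict_proba_frame(cohort.matrix.iloc[te])
            labels = pred.columns[np.argmax(pred.to_numpy(), axis=1)]
            scores.append(balanced_accuracy(y[te], labels))
        return float(np.mean(scores))

    fn.folds = folds
    return fn


def bootstrap_objective(
    learner_id: str,
    features: pd.DataFrame,
    labels,
    times: int = 10,
    seed: int = 0,
) -> Callable[[dict], float]:
    """Mean out-of-bag balanced accuracy over ``times`` bootstrap resamples.

    Each resample draws n samples with replacement for fitting and scores on
    the out-of-bag remainder. Resamples whose in-bag or out-of-bag part
    misses a class are redrawn (bounded retries) and otherwise skipped with a
    warning. The resample plan is frozen per call and exposed as
    ``fn.resamples``.
    """
    from .base_models import make_estimator

    if times < 1:
        raise ValueError("bootstrap times must be >= 1")
    x = features
    y = np.asarray(pd.Series(labels))
    n = len(y)
    classes = set(y)
    rng = np.random.default_rng(seed)
    resamples: list[tuple[np.ndarray, np.ndarray]] = []
    for t in range(times):
        for _attempt in range(25):
            inbag = rng.integers(0, n, size=n)
            oob = np.setdiff1d(np.arange(n), inbag)
            if len(oob) and set(y[inbag]) == classes and set(y[oob]) == classes:
                resamples.append((inbag, oob))
                break
        else:
            logger.warning("bootstrap resample %d degenerate after retries; skipped", t)

    def fn(params: dict) -> float:
        scores = []
        for inbag, oob in resamples:
            est = make_estimator(learner_id, params, seed=derive_seed(seed, "boot-fit"))
            est.fit(x.iloc[inbag], y[inbag])
            pred = est.predict_proba_frame(x.iloc[oob])
            plabels = pred.columns[np.argmax(pred.to_numpy(), axis=1)]
            scores.append(balanced_accuracy(y[oob], plabels))
        return float(np.mean(scores))

    fn.resamples = resamples
    return fn
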