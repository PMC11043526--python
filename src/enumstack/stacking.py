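"""Two-layer stacking: enumeration of base-model subsets, probability
meta-features, meta-learner fitting, and the ranked model catalogue.

Every subset of the selected base models of size >= 2 is enumerated
exhaustively — with five selected base models that is C(5,2)+C(5,3)+C(5,4)+
C(5,5) = 26 combinations — and each combination is paired with each of the
nine meta-learning algorithms, giving 26 x 9 = 234 stacked models. The
catalogue additionally carries the nine tuned single base models, 243
entries in total.

Meta-learners are trained on out-of-fold base probabilities (never on
refit-on-all predictions), which prevents the classic stacking leakage where
the second layer learns the base models' overfit. At test time base
probabilities come from base models refitted on the full training cohort.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .base_models import (
    DISPLAY_NAMES,
    ID_FROM_DISPLAY,
    TunedModel,
    make_estimator,
)
from .metrics import MetricReport, ProbabilityPrediction, mean_metric, metric_report
from .synthetic import LabeledCohort
from .tuning import SearchSpace, TuneProtocol, bootstrap_objective, tune
from .util import derive_seed, logger

__all__ = [
    "Combination",
    "StackedModel",
    "CatalogueEntry",
    "enumerate_combinations",
    "build_meta_features",
    "fit_stacked",
    "build_catalogue",
    "evaluate_catalogue",
    "predict",
    "stacked_name",
    "parse_stacked_name",
    "catalogue_frame",
]


@dataclass(frozen=True)
class Combination:
    """An ordered subset (size >= 2) of selected base-model algorithm ids."""

    member_ids: tuple[str, ...]

    def __post_init__(self):
        if len(self.member_ids) < 2:
            raise ValueError("a combination needs at least 2 members")
        if len(set(self.member_ids)) != len(self.member_ids):
            raise ValueError(f"duplicate member ids in {self.member_ids}")


def enumerate_combinations(member_ids: list[str], min_size: int = 2) -> list[Combination]:
    """All subsets of size >= ``min_size``, ordered by size then lexicographically."""
    ids = list(member_ids)
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate member ids: {ids}")
    if len(ids) < min_size:
        raise ValueError(f"need at least {min_size} members, got {len(ids)}")
    combos = [
        Combination(subset)
        for size in range(min_size, len(ids) + 1)
        for subset in sorted(itertools.combinations(sorted(ids), size))
    ]
    return combos


def stacked_name(combination: Combination, meta_algorithm_id: str) -> str:
    """Display name ``<members joined by '.'>-stacking-<meta>``."""
    members = ".".join(DISPLAY_NAMES.get(m, m) for m in combination.member_ids)
    return f"{members}-stacking-{DISPLAY_NAMES.get(meta_algorithm_id, meta_algorithm_id)}"


def parse_stacked_name(name: str) -> tuple[tuple[str, ...], str]:
    """Inverse of :func:`stacked_name`: name -> (member ids, meta id)."""
    members_part, sep, meta_part = name.rpartition("-stacking-")
    if not sep:
        raise ValueError(f"{name!r} is not a stacked-model name")
    members = tuple(ID_FROM_DISPLAY.get(m, m) for m in members_part.split("."))
    return members, ID_FROM_DISPLAY.get(meta_part, meta_part)


def build_meta_features(
    probs_by_model: dict[str, ProbabilityPrediction], combination: Combination
) -> pd.DataFrame:
    """Concatenate per-member probability blocks into the second-layer input.

    Columns are named ``<model_id>.<class_name>``; block order follows the
    combination's member order and all K class columns are kept per member.
    """
    blocks = []
    ref_ids = None
    for mid in combination.member_ids:
        if mid not in probs_by_model:
            raise KeyError(f"no probabilities for combination member {mid!r}")
        pred = probs_by_model[mid]
        if ref_ids is None:
            ref_ids = pred.sample_ids
        elif pred.sample_ids != ref_ids:
            raise ValueError(f"sample misalignment at member {mid!r}")
        block = pred.probs.copy()
        block.columns = [f"{mid}.{c}" for c in block.columns]
        blocks.append(block)
    return pd.concat(blocks, axis=1)


@dataclass
class StackedModel:
    """A base-model subset plus a fitted meta-learner over their probabilities."""

    combination: Combination
    base_models: dict[str, TunedModel]
    meta: TunedModel
    name: str

    @property
    def class_names(self) -> tuple[str, ...]:
        return self.meta.class_names

    @property
    def feature_names(self) -> tuple[str, ...]:
        """Raw-feature layout expected at the first layer."""
        return next(iter(self.base_models.values())).feature_names

    def predict(self, matrix: pd.DataFrame) -> ProbabilityPrediction:
        return predict(self, matrix)


def predict(stacked: StackedModel, matrix: pd.DataFrame) -> ProbabilityPrediction:
    """Two-stage prediction: raw features -> base probabilities -> meta output."""
    base_probs = {
        mid: stacked.base_models[mid].predict(matrix)
        for mid in stacked.combination.member_ids
    }
    meta_x = build_meta_features(base_probs, stacked.combination)
    return stacked.meta.predict(meta_x)


def fit_stacked(
    combination: Combination,
    train_cohort: LabeledCohort,
    base_fitted: dict[str, TunedModel],
    oof_probs: dict[str, ProbabilityPrediction],
    meta_algorithm_id: str,
    protocol: TuneProtocol,
    space: SearchSpace | None = None,
) -> StackedModel:
    """Tune and fit one meta-learner on the combination's OOF meta-features.

    The meta-learner is tuned with the bootstrap out-of-bag objective
    (default x10 resamples) and refitted on the full meta-feature matrix.
    """
    from .base_models import ALGORITHM_IDS, default_space

    if meta_algorithm_id not in ALGORITHM_IDS:
        raise KeyError(f"unknown meta algorithm {meta_algorithm_id!r}")
    missing = [m for m in combination.member_ids if m not in base_fitted or m not in oof_probs]
    if missing:
        raise KeyError(f"combination members without fitted model/OOF rows: {missing}")

    meta_x = build_meta_features(oof_probs, combination)
    y = np.asarray(train_cohort.labels)
    name = stacked_name(combination, meta_algorithm_id)
    boot_seed = derive_seed(protocol.seed, "boot", name)
    objective = bootstrap_objective(
        meta_algorithm_id, meta_x, y, times=protocol.bootstrap_times, seed=boot_seed
    )
    space = space or default_space(meta_algorithm_id)
    result = tune(objective, space, replace(protocol, seed=derive_seed(protocol.seed, "tune", name)))

    backend = make_estimator(
        meta_algorithm_id, result.best_params, seed=derive_seed(protocol.seed, "refit", name)
    )
    backend.fit(meta_x, y)
    meta = TunedModel(
        algorithm_id=meta_algorithm_id,
        hyperparameters=result.best_params,
        backend=backend,
        feature_names=tuple(meta_x.columns),
        class_names=backend.classes_,
        cv_report=None,
        seed=derive_seed(protocol.seed, "refit", name),
        tune_result=result,
    )
    base_subset = {m: base_fitted[m] for m in combination.member_ids}
    return StackedModel(combination=combination, base_models=base_subset, meta=meta, name=name)


@dataclass
class CatalogueEntry:
    """One of the 243 catalogue models: either a stacked model or a base model."""

    name: str
    kind: str  # "stacked" | "base"
    model: StackedModel | TunedModel
    test_reports: dict[str, MetricReport] = field(default_factory=dict)
    rank_score: float = float("nan")

    def predict(self, matrix: pd.DataFrame) -> ProbabilityPrediction:
        return self.model.predict(matrix)


def build_catalogue(
    selected_base: list[TunedModel],
    train_cohort: LabeledCohort,
    base_fitted_all: list[TunedModel],
    oof_probs: dict[str, ProbabilityPrediction],
    meta_ids: tuple[str, ...],
    protocol: TuneProtocol,
    spaces: dict[str, SearchSpace] | None = None,
) -> list[CatalogueEntry]:
    """Assemble the full model catalogue.

    One stacked entry per (combination of selected base models x meta
    algorithm) plus one entry per tuned single base model: with 5 selected
    base models and 9 meta algorithms that is 234 + 9 = 243 entries. Entries
    whose meta-fit fails are logged and skipped.
    """
    combos = enumerate_combinations([m.algorithm_id for m in selected_base])
    base_map = {m.algorithm_id: m for m in selected_base}
    spaces = spaces or {}
    entries: list[CatalogueEntry] = []
    for combo in combos:
        for meta_id in meta_ids:
            try:
                sm = fit_stacked(
                    combo,
                    train_cohort,
                    base_map,
                    oof_probs,
                    meta_id,
                    protocol,
                    space=spaces.get(meta_id),
                )
            except Exception as exc:  # noqa: BLE001 — catalogue robustness contract
                logger.warning(
                    "catalogue entry %s failed and is skipped: %s",
                    stacked_name(combo, meta_id),
                    exc,
                )
                continue
            entries.append(CatalogueEntry(name=sm.name, kind="stacked", model=sm))
    for bm in base_fitted_all:
        entries.append(
            CatalogueEntry(name=DISPLAY_NAMES.get(bm.algorithm_id, bm.algorithm_id), kind="base", model=bm)
        )
    names = [e.name for e in entries]
    if len(set(names)) != len(names):
        raise RuntimeError("catalogue names are not unique")
    logger.info("catalogue built: %d entries (%d stacked)", len(entries), len(combos) * len(meta_ids))
    return entries


def _aligned(matrix: pd.DataFrame, feature_names: tuple[str, ...], cohort_id: str) -> pd.DataFrame:
    missing = [f for f in feature_names if f not in matrix.columns]
    extra = [f for f in matrix.columns if f not in feature_names]
    if missing:
        raise ValueError(
            f"cohort {cohort_id}: missing features {missing[:5]}..., extra {extra[:5]}..."
        )
    return matrix.loc[:, list(feature_names)]


def evaluate_catalogue(
    catalogue: list[CatalogueEntry], test_cohorts: list[LabeledCohort]
) -> list[CatalogueEntry]:
    """Score every entry on every test cohort and rank by the mean metric.

    ``rank_score`` is the grand mean of the 11 metrics across the test
    cohorts; the returned list is sorted by descending rank score with ties
    broken by name.
    """
    if not test_cohorts:
        raise ValueError("evaluate_catalogue needs at least one test cohort")
    for entry in catalogue:
        feats = (
            entry.model.feature_names
            if isinstance(entry.model, StackedModel)
            else entry.model.feature_names
        )
        entry.test_reports = {}
        for cohort in test_cohorts:
            x = _aligned(cohort.matrix, feats, cohort.cohort_id)
            pred = entry.predict(x)
            entry.test_reports[cohort.cohort_id] = metric_report(cohort.labels, pred)
        entry.rank_score = mean_metric(list(entry.test_reports.values()))
    return sorted(catalogue, key=lambda e: (-e.rank_score, e.name))


def catalogue_frame(ranked: list[CatalogueEntry]) -> pd.DataFrame:
    """Flatten a ranked catalogue into the catalogue.csv layout."""
    rows = []
    for rank, entry in enumerate(ranked, start=1):
        row: dict = {"rank": rank, "name": entry.name, "kind": entry.kind, "rank_score": entry.rank_score}
        for cohort_id, report in entry.test_reports.items():
            for metric, value in report.as_dict().items():
                row[f"{cohort_id}.{metric}"] = value
        rows.append(row)
    return pd.DataFrame(rows)
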