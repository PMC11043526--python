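"""Synthetic multi-cohort expression data with known class structure.

Generates labelled cohorts that mimic log2-TPM expression tables for a
K-class molecular-subtype problem (default three classes, CL / MES / PN):
a subset of informative genes carries class-dependent Gaussian mean shifts,
the remaining genes are pure noise, and each cohort may carry an additive
batch offset. Values are drawn directly on the normalized (log2-TPM-like)
scale with unit variance; no count model is simulated, because the
classification framework consumes already-normalized expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .util import logger

__all__ = ["SyntheticSpec", "LabeledCohort", "generate_cohorts", "worked_fixture"]

#: Default class names for the three-subtype problem.
DEFAULT_CLASS_NAMES = ("CL", "MES", "PN")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters of a synthetic multi-cohort experiment.

    Parameters
    ----------
    n_samples_per_cohort
        One entry per cohort; the first cohort conventionally plays the
        training role.
    n_classes
        Number of subtype labels (K >= 2).
    n_features
        Total gene count.
    n_informative
        How many genes carry class signal; must not exceed ``n_features``.
    effect_size
        Class mean shift of informative genes, in units of the within-class
        standard deviation (which is 1).
    batch_offsets
        Additive per-cohort offset applied to every matrix value; ``None``
        means all zeros.
    class_proportions
        Sampling probabilities of the classes; ``None`` means uniform.
    seed
        Seed for all randomness in generation.
    """

    n_samples_per_cohort: tuple[int, ...] = (100, 100)
    n_classes: int = 3
    n_features: int = 100
    n_informative: int = 20
    effect_size: float = 1.0
    batch_offsets: tuple[float, ...] | None = None
    class_proportions: tuple[float, ...] | None = None
    seed: int = 0
    class_names: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.n_samples_per_cohort or any(
            int(n) <= 0 for n in self.n_samples_per_cohort
        ):
            raise ValueError("n_samples_per_cohort: every entry must be a positive integer")
        if self.n_classes < 2:
            raise ValueError("n_classes: must be >= 2")
        if self.n_features <= 0:
            raise ValueError("n_features: must be positive")
        if not 0 <= self.n_informative <= self.n_features:
            raise ValueError("n_informative: must satisfy 0 <= n_informative <= n_features")
        if self.effect_size < 0:
            raise ValueError("effect_size: must be non-negative")
        if self.batch_offsets is not None and len(self.batch_offsets) != len(
            self.n_samples_per_cohort
        ):
            raise ValueError("batch_offsets: needs one offset per cohort")
        if self.class_proportions is not None:
            p = np.asarray(self.class_proportions, dtype=float)
            if len(p) != self.n_classes:
                raise ValueError("class_proportions: length must equal n_classes")
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("class_proportions: must be non-negative and sum to 1")
        if self.class_names and len(self.class_names) != self.n_classes:
            raise ValueError("class_names: length must equal n_classes")

    @property
    def resolved_class_names(self) -> tuple[str, ...]:
        if self.class_names:
            return self.class_names
        if self.n_classes == 3:
            return DEFAULT_CLASS_NAMES
        return tuple(f"class{k + 1}" for k in range(self.n_classes))


@dataclass
class LabeledCohort:
    """An expression matrix (samples x genes) with per-sample subtype labels."""

    cohort_id: str
    matrix: pd.DataFrame
    labels: pd.Series

    def __post_init__(self) -> None:
        if self.matrix.isna().any().any():
            raise ValueError(f"cohort {self.cohort_id}: matrix contains missing values")
        if len(self.labels) != len(self.matrix):
            raise ValueError(
                f"cohort {self.cohort_id}: {len(self.labels)} labels for "
                f"{len(self.matrix)} samples"
            )
        if self.matrix.columns.duplicated().any():
            raise ValueError(f"cohort {self.cohort_id}: duplicate feature names")
        self.labels = pd.Series(
            np.asarray(self.labels, dtype=object), index=self.matrix.index, name="label"
        )

    @property
    def class_names(self) -> tuple[str, ...]:
        """Observed class names, in lexicographic order."""
        return tuple(sorted(set(self.labels)))

    @property
    def feature_names(self) -> tuple[str, ...]:
        return tuple(self.matrix.columns)

    def subset_features(self, features: list[str] | tuple[str, ...]) -> "LabeledCohort":
        missing = [f for f in features if f not in self.matrix.columns]
        if missing:
            raise KeyError(f"cohort {self.cohort_id}: unknown features {missing}")
        return LabeledCohort(self.cohort_id, self.matrix.loc[:, list(features)].copy(), self.labels.copy())


def _informative_means(n_classes: int, n_informative: int, effect_size: float) -> np.ndarray:
    """Class-conditional means of the informative block (K x n_informative).

    The informative genes are split into K contiguous sub-blocks; class k is
    shifted by ``effect_size`` on sub-block k, so every pair of classes
    differs in mean on at least one sub-block and all K classes are mutually
    separable once the effect is large.
    """
    means = np.zeros((n_classes, n_informative))
    if n_informative == 0:
        return means
    bounds = np.linspace(0, n_informative, n_classes + 1).astype(int)
    for k in range(n_classes):
        means[k, bounds[k] : bounds[k + 1]] = effect_size
    return means


def generate_cohorts(spec: SyntheticSpec) -> list[LabeledCohort]:
    """Draw one labelled cohort per entry of ``spec.n_samples_per_cohort``.

    Labels are multinomial draws from ``class_proportions`` (uniform by
    default); informative genes follow class-conditional Gaussians with unit
    SD; noise genes are standard Gaussian; the cohort batch offset is added
    to every value. Bit-identical under a fixed spec (including seed).
    """
    rng = np.random.default_rng(spec.seed)
    class_names = spec.resolved_class_names
    props = (
        np.full(spec.n_classes, 1.0 / spec.n_classes)
        if spec.class_proportions is None
        else np.asarray(spec.class_proportions, dtype=float)
    )
    offsets = spec.batch_offsets or (0.0,) * len(spec.n_samples_per_cohort)
    means = _informative_means(spec.n_classes, spec.n_informative, spec.effect_size)
    feat_names = [f"gene{j + 1:04d}" for j in range(spec.n_features)]

    cohorts: list[LabeledCohort] = []
    for c, (n, offset) in enumerate(zip(spec.n_samples_per_cohort, offsets)):
        cohort_id = f"cohort{c + 1}"
        y = rng.choice(spec.n_classes, size=n, p=props)
        x = rng.standard_normal((n, spec.n_features))
        if spec.n_informative:
            x[:, : spec.n_informative] += means[y]
        x += offset
        sample_ids = [f"{cohort_id}_s{i + 1:04d}" for i in range(n)]
        matrix = pd.DataFrame(x, index=sample_ids, columns=feat_names)
        labels = pd.Series([class_names[k] for k in y], index=sample_ids, name="label")
        cohorts.append(LabeledCohort(cohort_id, matrix, labels))
        logger.debug("generated %s: %d samples x %d features", cohort_id, n, spec.n_features)
    return cohorts


def worked_fixture() -> LabeledCohort:
    """A fixed 12-sample x 6-feature, 3-class cohort with 4 samples per class.

    Used throughout the unit tests for exact metric and shape assertions;
    content is identical on every call. Classes are named A/B/C and feature
    f1 increases with the class index so simple learners can separate it.
    """
    rng = np.random.default_rng(20240411)
    labels = ["A"] * 4 + ["B"] * 4 + ["C"] * 4
    y = np.repeat([0, 1, 2], 4)
    x = rng.standard_normal((12, 6)) * 0.3
    x[:, 0] += 3.0 * y  # f1 tracks the class
    x[:, 1] -= 1.5 * y
    sample_ids = [f"fx_s{i + 1:02d}" for i in range(12)]
    matrix = pd.DataFrame(x, index=sample_ids, columns=[f"f{j + 1}" for j in range(6)])
    return LabeledCohort("worked_fixture", matrix, pd.Series(labels, index=sample_ids))
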