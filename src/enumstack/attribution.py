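"""Model-agnostic Shapley additive attributions on the probability scale.

The value of a feature coalition S for a sample x is the expected model
output when features in S take x's values and the remaining features are
imputed from a background table (mean over background rows):

    v(S) = E_b [ f(x_S, b_{~S}) ]

Shapley values are the permutation-average of marginal contributions to
v. Two estimators are provided:

* :func:`shapley_sampling` — samples feature permutations (or enumerates all
  of them when the budget covers F!), caching coalition values. Marginal
  contributions telescope within each permutation, so local accuracy
  (base value + sum of attributions = model output) holds by construction;
  a final residual redistribution absorbs floating-point drift.
* :func:`exact_shapley_oracle` — exact enumeration of all 2^F coalitions
  with the combinatorial Shapley weights; limited to <= 12 features.

The estimator is model-agnostic on purpose: the object being explained is
the composite two-layer stacking pipeline in original feature space, not a
single tree model, so tree-path-specific algorithms do not apply.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

__all__ = [
    "Attribution",
    "ImportanceTable",
    "shapley_sampling",
    "exact_shapley_oracle",
    "importance_table",
    "attributions_frame",
]

#: prediction function: feature table -> per-class probability table
ModelFn = Callable[[pd.DataFrame], pd.DataFrame]


@dataclass(frozen=True)
class Attribution:
    """Signed contribution of one feature to one sample's class probability."""

    sample_id: object
    class_name: str
    feature_name: str
    shap_value: float
    feature_value: float
    base_value: float


@dataclass
class ImportanceTable:
    """Per-class feature ranking by mean absolute attribution."""

    per_class: dict[str, pd.DataFrame]  # class -> (feature, mean_abs_shap) descending
    dependence: pd.DataFrame  # long records (class, feature, feature_value, shap_value)


def _coalition_value_fn(model: ModelFn, background: pd.DataFrame, x_row: pd.Series):
    """Returns v(S) -> per-class mean output with non-members imputed from background."""
    cache: dict[frozenset, np.ndarray] = {}
    features = list(background.columns)

    def value(coalition: frozenset) -> np.ndarray:
        if coalition not in cache:
            hybrid = background.copy()
            for f in coalition:
                hybrid[f] = x_row[f]
            out = model(hybrid.loc[:, features])
            cache[coalition] = np.asarray(out, dtype=float).mean(axis=0)
        return cache[coalition]

    return value


def _class_columns(model: ModelFn, background: pd.DataFrame) -> list[str]:
    out = model(background.iloc[:1])
    return list(out.columns)


def shapley_sampling(
    model: ModelFn,
    background: pd.DataFrame,
    samples: pd.DataFrame,
    n_permutations: int = 200,
    seed: int = 0,
) -> list[Attribution]:
    """Permutation-sampling Shapley attributions for every (sample, class).

    When ``n_permutations >= F!`` the full permutation set is enumerated
    exactly once each, making the estimate exact. Coalition values are
    cached per sample, so the cost is bounded by unique coalitions rather
    than permutations.
    """
    if background.empty:
        raise ValueError("background table must be non-empty")
    if list(samples.columns) != list(background.columns):
        raise ValueError("samples and background must share the same feature layout")
    features = list(background.columns)
    f_count = len(features)
    classes = _class_columns(model, background)
    rng = np.random.default_rng(seed)

    total_perms = math.factorial(f_count)
    if n_permutations >= total_perms:
        perms = list(itertools.permutations(range(f_count)))
    else:
        perms = [tuple(rng.permutation(f_count)) for _ in range(n_permutations)]

    records: list[Attribution] = []
    for sid, x_row in samples.iterrows():
        value = _coalition_value_fn(model, background, x_row)
        base = value(frozenset())
        full = value(frozenset(features))
        phi = np.zeros((f_count, len(classes)))
        for perm in perms:
            coalition: set[str] = set()
            prev = base
            for j in perm:
                coalition.add(features[j])
                cur = value(frozenset(coalition))
                phi[j] += cur - prev
                prev = cur
        phi /= len(perms)
        # redistribute any floating-point residual so local accuracy is exact
        residual = (full - base) - phi.sum(axis=0)
        phi += residual / f_count
        for k, cls in enumerate(classes):
            for j, feat in enumerate(features):
                records.append(
                    Attribution(
                        sample_id=sid,
                        class_name=cls,
                        feature_name=feat,
                        shap_value=float(phi[j, k]),
                        feature_value=float(x_row[feat]),
                        base_value=float(base[k]),
                    )
                )
    return records


def exact_shapley_oracle(
    model: ModelFn,
    background: pd.DataFrame,
    sample: pd.Series,
    class_name: str,
) -> dict[str, float]:
    """Exact Shapley values for one sample and one class by 2^F enumeration."""
    features = list(background.columns)
    f_count = len(features)
    if f_count > 12:
        raise ValueError(
            f"{f_count} features is too many for exact enumeration; "
            "use shapley_sampling instead"
        )
    classes = _class_columns(model, background)
    k = classes.index(class_name)
    value = _coalition_value_fn(model, background, sample)

    phi = {f: 0.0 for f in features}
    for feat in features:
        others = [f for f in features if f != feat]
        for size in range(len(others) + 1):
            weight = (
                math.factorial(size) * math.factorial(f_count - size - 1) / math.factorial(f_count)
            )
            for subset in itertools.combinations(others, size):
                s = frozenset(subset)
                gain = value(s | {feat})[k] - value(s)[k]
                phi[feat] += weight * gain
    return phi


def attributions_frame(attributions: list[Attribution]) -> pd.DataFrame:
    """Long-format table of attribution records."""
    return pd.DataFrame(
        {
            "sample_id": [a.sample_id for a in attributions],
            "class": [a.class_name for a in attributions],
            "feature": [a.feature_name for a in attributions],
            "feature_value": [a.feature_value for a in attributions],
            "shap_value": [a.shap_value for a in attributions],
            "base_value": [a.base_value for a in attributions],
        }
    )


def importance_table(attributions: list[Attribution]) -> ImportanceTable:
    """Rank features per class by mean |attribution| over explained samples."""
    if not attributions:
        raise ValueError("importance_table needs at least one attribution record")
    frame = attributions_frame(attributions)
    per_class: dict[str, pd.DataFrame] = {}
    for cls, grp in frame.groupby("class", sort=True):
        means = (
            grp.assign(abs_shap=grp["shap_value"].abs())
            .groupby("feature", sort=True)["abs_shap"]
            .mean()
            .sort_values(ascending=False, kind="stable")
        )
        per_class[cls] = means.rename("mean_abs_shap").reset_index()
    dependence = frame.loc[:, ["class", "feature", "feature_value", "shap_value"]].copy()
    return ImportanceTable(per_class=per_class, dependence=dependence)
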