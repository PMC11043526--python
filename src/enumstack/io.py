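"""Table readers/writers and model-bundle persistence.

Expression tables are plain TSV/CSV (delimiter chosen by extension): samples
in rows, first column the sample id, a ``label`` column with the subtype,
and every other column a numeric feature. ``--transpose`` accepts
genes-in-rows layouts.

A model bundle is a directory holding a human-readable ``manifest.json``
(schema version, model name, algorithm ids, hyperparameters, feature and
class names, seeds, metric reports) next to the serialized fitted state;
loading a saved bundle reproduces predictions bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import joblib
import pandas as pd

from .base_models import TunedModel
from .metrics import MetricReport
from .stacking import CatalogueEntry, StackedModel
from .synthetic import LabeledCohort
from .util import logger

__all__ = [
    "read_labeled_table",
    "write_labeled_table",
    "save_bundle",
    "load_bundle",
    "SCHEMA_VERSION",
]

SCHEMA_VERSION = 1


def _delimiter(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_labeled_table(
    path: str | Path, label_column: str = "label", transpose: bool = False
) -> LabeledCohort:
    """Read a labelled expression table into a cohort.

    With ``transpose=True`` the file is genes-in-rows and the label row is
    identified by ``label_column`` in the first column.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    table = pd.read_csv(path, sep=_delimiter(path), index_col=0)
    if transpose:
        table = table.T
    if table.index.duplicated().any():
        dup = table.index[table.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate sample id {dup!r}")
    if label_column not in table.columns:
        raise ValueError(f"{path}: missing label column {label_column!r}")
    labels = table[label_column].astype(str)
    matrix = table.drop(columns=[label_column])
    if matrix.columns.duplicated().any():
        dup = matrix.columns[matrix.columns.duplicated()][0]
        raise ValueError(f"{path}: duplicate feature name {dup!r}")
    for col in matrix.columns:
        numeric = pd.to_numeric(matrix[col], errors="coerce")
        if numeric.isna().any():
            row = matrix.index[numeric.isna()][0]
            raise ValueError(f"{path}: non-numeric value at row {row!r}, column {col!r}")
        matrix[col] = numeric.astype(float)
    return LabeledCohort(path.stem, matrix, labels)


def write_labeled_table(
    cohort: LabeledCohort, path: str | Path, transpose: bool = False
) -> None:
    """Write a cohort as TSV/CSV (label last; transposed layout optional)."""
    path = Path(path)
    table = cohort.matrix.copy()
    table["label"] = cohort.labels.to_numpy()
    if transpose:
        table = table.T
    table.to_csv(path, sep=_delimiter(path))


# ---------------------------------------------------------------------------
# model bundles


@dataclass
class ModelBundle:
    manifest: dict
    model: StackedModel | TunedModel


def _report_dict(report: MetricReport | None) -> dict | None:
    return None if report is None else report.as_dict()


def _manifest_for(model: StackedModel | TunedModel, name: str, extra: dict | None) -> dict:
    if isinstance(model, StackedModel):
        manifest = {
            "schema_version": SCHEMA_VERSION,
            "kind": "stacked",
            "name": name,
            "member_ids": list(model.combination.member_ids),
            "meta_algorithm": model.meta.algorithm_id,
            "meta_hyperparameters": model.meta.hyperparameters,
            "base_hyperparameters": {
                m: model.base_models[m].hyperparameters for m in model.combination.member_ids
            },
            "feature_names": list(model.feature_names),
            "class_names": list(model.class_names),
            "seeds": {
                "meta": model.meta.seed,
                **{m: model.base_models[m].seed for m in model.combination.member_ids},
            },
        }
    else:
        manifest = {
            "schema_version": SCHEMA_VERSION,
            "kind": "base",
            "name": name,
            "algorithm_id": model.algorithm_id,
            "hyperparameters": model.hyperparameters,
            "feature_names": list(model.feature_names),
            "class_names": list(model.class_names),
            "seeds": {"fit": model.seed},
            "cv_report": _report_dict(model.cv_report),
        }
    manifest.update(extra or {})
    return manifest


def save_bundle(
    model: StackedModel | TunedModel | CatalogueEntry,
    directory: str | Path,
    extra_manifest: dict | None = None,
) -> Path:
    """Persist a fitted model plus manifest under ``directory``."""
    if isinstance(model, CatalogueEntry):
        extra_manifest = {
            **(extra_manifest or {}),
            "rank_score": model.rank_score,
            "test_reports": {c: r.as_dict() for c, r in model.test_reports.items()},
        }
        name, model = model.name, model.model
    else:
        name = getattr(model, "name", getattr(model, "algorithm_id", "model"))
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = _manifest_for(model, name, extra_manifest)
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    joblib.dump(model, directory / "model.joblib")
    logger.info("bundle saved to %s", directory)
    return directory


def load_bundle(directory: str | Path) -> ModelBundle:
    """Load a bundle; predictions of the loaded model match the original."""
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest.json in {directory}")
    manifest = json.loads(manifest_path.read_text())
    found = manifest.get("schema_version")
    if found != SCHEMA_VERSION:
        raise ValueError(
            f"bundle schema version {found} is incompatible with {SCHEMA_VERSION}"
        )
    model = joblib.load(directory / "model.joblib")
    return ModelBundle(manifest=manifest, model=model)
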