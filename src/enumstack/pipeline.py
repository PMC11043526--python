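"""End-to-end workflow: feature selection -> base fitting -> top-5 selection
-> catalogue enumeration -> multi-cohort evaluation -> ranked outputs."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import base_models, feature_selection, stacking
from .io import save_bundle
from .stacking import CatalogueEntry, catalogue_frame, evaluate_catalogue
from .synthetic import LabeledCohort
from .tuning import SearchSpace, TuneProtocol
from .util import derive_seed, logger

__all__ = ["RunConfig", "PipelineResult", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one catalogue run needs; a single seed fans out everywhere."""

    base_algorithms: tuple[str, ...] = base_models.ALGORITHM_IDS
    meta_algorithms: tuple[str, ...] = base_models.ALGORITHM_IDS
    top_k: int = 5
    base_protocol: TuneProtocol = field(default_factory=TuneProtocol)
    meta_protocol: TuneProtocol = field(
        default_factory=lambda: TuneProtocol(resampling="bootstrap")
    )
    feature_selection: bool = False
    selection_mode: str = "union"
    selection_target_size: int = 10
    spaces: dict[str, SearchSpace] | None = None
    seed: int = 0

    def config_hash(self) -> str:
        payload = {
            "base_algorithms": list(self.base_algorithms),
            "meta_algorithms": list(self.meta_algorithms),
            "top_k": self.top_k,
            "base_protocol": vars(self.base_protocol) | {},
            "meta_protocol": vars(self.meta_protocol) | {},
            "feature_selection": self.feature_selection,
            "selection_mode": self.selection_mode,
            "seed": self.seed,
        }
        blob = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


@dataclass
class PipelineResult:
    ranked_catalogue: list[CatalogueEntry]
    base_fitted: list[base_models.TunedModel]
    selected_base: list[base_models.TunedModel]
    selected_features: tuple[str, ...] | None
    catalogue: pd.DataFrame


def run_pipeline(
    config: RunConfig,
    train_cohort: LabeledCohort,
    test_cohorts: list[LabeledCohort],
    out_dir: str | Path | None = None,
) -> PipelineResult:
    """Run the whole enumeration framework on one training + N test cohorts.

    Writes ``catalogue.csv`` (with a config-hash/seed sidecar) and the
    top-ranked model's bundle when ``out_dir`` is given.
    """
    seed = config.seed
    spaces = config.spaces or {}

    selected_features: tuple[str, ...] | None = None
    if config.feature_selection:
        logger.info("stage: feature selection (%s)", config.selection_mode)
        schedule = feature_selection.RFESchedule(
            step=0.2, target_size=config.selection_target_size
        )
        a = feature_selection.svm_rfe(train_cohort, schedule, seed=derive_seed(seed, "rfe"))
        b = feature_selection.rf_backward(train_cohort, seed=derive_seed(seed, "rfb"))
        combined = feature_selection.combine_selections(a, b, mode=config.selection_mode)
        selected_features = combined.selected
        train_cohort = train_cohort.subset_features(selected_features)
        test_cohorts = [c.subset_features(selected_features) for c in test_cohorts]

    logger.info("stage: base model fitting (%d algorithms)", len(config.base_algorithms))
    base_protocol = replace(config.base_protocol, seed=derive_seed(seed, "base"))
    fitted = [
        base_models.fit_base(aid, train_cohort, base_protocol, space=spaces.get(aid))
        for aid in config.base_algorithms
    ]

    logger.info("stage: top-%d base selection", config.top_k)
    selected = base_models.select_top_base(fitted, config.top_k)

    logger.info("stage: out-of-fold probabilities for %d selected models", len(selected))
    oof_seed = derive_seed(base_protocol.seed, "oof")
    oof = {
        m.algorithm_id: base_models.oof_probabilities(
            m.algorithm_id,
            m.hyperparameters,
            train_cohort,
            k=base_protocol.cv_folds,
            seed=oof_seed,
        )
        for m in selected
    }

    logger.info("stage: catalogue build (%d meta algorithms)", len(config.meta_algorithms))
    meta_protocol = replace(config.meta_protocol, seed=derive_seed(seed, "meta"))
    catalogue = stacking.build_catalogue(
        selected,
        train_cohort,
        fitted,
        oof,
        config.meta_algorithms,
        meta_protocol,
        spaces=spaces,
    )

    logger.info("stage: evaluation on %d test cohorts", len(test_cohorts))
    ranked = evaluate_catalogue(catalogue, test_cohorts)
    frame = catalogue_frame(ranked)

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out_dir / "catalogue.csv", index=False)
        sidecar = {
            "config_hash": config.config_hash(),
            "seed": seed,
            "n_entries": len(ranked),
            "top_model": ranked[0].name,
        }
        (out_dir / "catalogue.meta.json").write_text(json.dumps(sidecar, indent=2))
        save_bundle(
            ranked[0],
            out_dir / "top_model",
            extra_manifest={"config_hash": config.config_hash(), "global_seed": seed},
        )
        if selected_features is not None:
            (out_dir / "selected_features.txt").write_text("\n".join(selected_features) + "\n")

    return PipelineResult(
        ranked_catalogue=ranked,
        base_fitted=fitted,
        selected_base=selected,
        selected_features=selected_features,
        catalogue=frame,
    )
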