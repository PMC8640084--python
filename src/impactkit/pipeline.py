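"""End-to-end pipeline: simulate -> preprocess -> featurize -> train ->
evaluate -> explain, with config hashing and per-stage provenance.

``run_pipeline`` executes the stages in order on a synthetic corpus and
writes five artifacts to a run directory: the corpus (session JSON), the
feature matrix (CSV), the tuned model (JSON), the evaluation report (JSON)
and the attribution summary (JSON).  Every artifact is stamped with the
configuration hash and global seed, so a rerun with the same configuration
reproduces identical results.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .capture_model import write_capture_file
from .evaluation import EvalReport, evaluate_model
from .features import (
    FeatureConfig,
    apply_standardizer,
    assemble_feature_matrix,
    fit_standardizer,
    generate_kernels,
)
from .interpretation import aggregate_attributions, attribution_summary
from .modeling import (
    TunedModel,
    baseline_sweep,
    build_dataset_bundle,
    default_roster,
    select_estimator,
    tune_estimator,
)
from .preprocess import TriageConfig, TriggerConfig, process_capture
from .synthetic_data import SimConfig, generate_corpus

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PipelineConfig:
    """All stage configurations plus the global seed.

    The global seed drives every stage's randomness (simulation, balancing,
    splitting, CV folding, candidate sampling, bootstrap resampling), so a
    fixed configuration is end-to-end deterministic.
    """

    sim: SimConfig = field(default_factory=SimConfig)
    triage: TriageConfig = field(default_factory=TriageConfig)
    trigger: TriggerConfig = field(default_factory=TriggerConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    n_candidates: int = 50
    folds: int = 5
    n_boot: int = 10_000
    top_k: int = 50
    roster: str = "compact"  # "compact" or "full"
    seed: int = 0

    @classmethod
    def synthetic_study(cls, seed: int = 0, n_captures: int = 2000) -> "PipelineConfig":
        """The desk-scale synthetic validation study configuration.

        A 2,000-capture corpus at the reference class imbalance, 100 shared
        kernels per signal, a 20-candidate randomized search and 2,000
        bootstrap resamples — the problem sizes used for the package's own
        end-to-end validation (see docs/methods.md).
        """
        return cls(
            sim=SimConfig(n_captures=n_captures, seed=seed),
            features=FeatureConfig(n_kernels=100),
            n_candidates=20,
            folds=5,
            n_boot=2000,
            seed=seed,
        )

    def with_seed(self, seed: int) -> "PipelineConfig":
        return dataclasses.replace(
            self, seed=seed, sim=dataclasses.replace(self.sim, seed=seed)
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class PipelineResult:
    """In-memory handles to everything a pipeline run produced."""

    config: PipelineConfig
    captures: list
    truths: list
    processed: list
    features: pd.DataFrame  # standardized
    bundle: object
    sweep: object
    selected: str
    model: TunedModel
    report: EvalReport
    attribution: object
    triage_stats: dict
    artifacts: dict


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(cfg: PipelineConfig, out_dir=None) -> PipelineResult:
    """Execute all stages in order; optionally persist artifacts to
    ``out_dir``.  Any stage failure aborts with the stage name attached."""
    stage = "simulate"
    try:
        sim = dataclasses.replace(cfg.sim, seed=cfg.seed) if cfg.sim.seed != cfg.seed else cfg.sim
        captures, truths, calibrations = generate_corpus(sim)
        logger.info("simulate: %d captures", len(captures))

        stage = "preprocess"
        cal = calibrations[captures[0].device_id]
        processed = [process_capture(c, cal, cfg.triage) for c in captures]
        kept = [p for p in processed if p.triage_passed]
        triage_stats = {
            "n_captures": len(processed),
            "n_triage_passed": len(kept),
            "n_triage_rejected": len(processed) - len(kept),
        }
        logger.info(
            "preprocess: %(n_triage_passed)d passed / %(n_triage_rejected)d "
            "rejected by triage",
            triage_stats,
        )

        stage = "featurize"
        kernels = generate_kernels(
            cfg.features.n_kernels,
            cfg.seed,
            cfg.features.kernel_input_length,
        )
        raw_features = assemble_feature_matrix(kept, kernels, cfg.features)
        y = np.array([1 if p.label == "hit" else 0 for p in kept])
        sessions = [p.session_id for p in kept]

        stage = "dataset"
        bundle = build_dataset_bundle(
            y, sessions, sim.holdout_session_id, seed=cfg.seed
        )
        std = fit_standardizer(raw_features, bundle.train)
        features = apply_standardizer(std, raw_features)
        logger.info(
            "dataset: balanced %d+%d train/val/test = %d/%d/%d, rest %d, holdout %d",
            int(y[bundle.train].sum()),
            int((1 - y[bundle.train]).sum()),
            bundle.train.size,
            bundle.validation.size,
            bundle.test.size,
            bundle.rest.size,
            bundle.holdout.size,
        )

        stage = "select"
        roster = default_roster(cfg.seed, compact=(cfg.roster == "compact"))
        sweep = baseline_sweep(features, bundle, roster)
        selected = select_estimator(sweep)

        stage = "tune"
        model = tune_estimator(
            features, bundle, cfg.n_candidates, cfg.folds, cfg.seed
        )

        stage = "evaluate"
        report = evaluate_model(model, features, bundle, cfg.n_boot, cfg.seed)

        stage = "explain"
        attribution = attribution_summary(
            model, features, bundle.validation, k=cfg.top_k
        )
    except Exception as e:
        if isinstance(e, PipelineStageError):
            raise
        raise PipelineStageError(stage, e) from e

    artifacts = {}
    if out_dir is not None:
        artifacts = _write_artifacts(
            Path(out_dir), cfg, captures, calibrations, features, model, report,
            attribution, sweep, triage_stats,
        )
    return PipelineResult(
        config=cfg,
        captures=captures,
        truths=truths,
        processed=processed,
        features=features,
        bundle=bundle,
        sweep=sweep,
        selected=selected,
        model=model,
        report=report,
        attribution=attribution,
        triage_stats=triage_stats,
        artifacts=artifacts,
    )


def _write_artifacts(
    out_dir: Path, cfg, captures, calibrations, features, model, report,
    attribution, sweep, triage_stats,
) -> dict:
    out_dir.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": cfg.config_hash(), "seed": cfg.seed, "impactkit": __version__}

    corpus_path = out_dir / "corpus.captures.json"
    write_capture_file(
        captures,
        corpus_path,
        calibration=calibrations[captures[0].device_id],
        header_extra=stamp,
    )

    features_path = out_dir / "features.csv"
    features.to_csv(features_path)

    model_path = out_dir / "model.json"
    booster_path = out_dir / "model.booster.json"
    model.model.get_booster().save_model(booster_path)
    with open(model_path, "w") as fh:
        json.dump(
            {
                **stamp,
                "algorithm": model.algorithm_id,
                "params": model.params,
                "cv_mcc": model.cv_mcc,
                "n_candidates": model.n_candidates,
                "folds": model.folds,
                "booster_file": booster_path.name,
            },
            fh,
            indent=1,
        )

    report_path = out_dir / "report.json"
    with open(report_path, "w") as fh:
        json.dump({**stamp, **report.to_dict(), "triage": triage_stats}, fh, indent=1)

    attr_path = out_dir / "attribution.json"
    with open(attr_path, "w") as fh:
        json.dump(
            {
                **stamp,
                **attribution.to_dict(),
                "by_family": aggregate_attributions(attribution, "family").to_dict(),
                "by_sensor": aggregate_attributions(attribution, "sensor").to_dict(),
                "by_frequency_band": aggregate_attributions(
                    attribution, "frequency_band"
                ).to_dict(),
            },
            fh,
            indent=1,
        )

    sweep_path = out_dir / "sweep.csv"
    sweep.table.to_csv(sweep_path)

    return {
        "corpus": corpus_path,
        "features": features_path,
        "model": model_path,
        "report": report_path,
        "attribution": attr_path,
        "sweep": sweep_path,
    }
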