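"""End-to-end orchestration: simulate -> features -> train -> predict -> evaluate.

Every run writes a deterministic artifact set (features CSV, model file,
predictions CSV, diagnostic report JSON, provenance log) into a run
directory; stage failures abort with a stage-named error carrying a
distinct exit code per stage family.
"""

from __future__ import annotations

import hashlib
import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .classify import (
    DEFAULT_N_BINS,
    DEFAULT_N_TREES,
    DEFAULT_RF_SEED,
    default_bins,
    extract_features,
    feature_matrix,
    predict_slide_grade,
    train_slide_classifier,
)
from .core import RiskStratum, SEVERITY_ORDER, SlideGrade
from .detection import DEFAULT_DEDUP_IOU
from .evaluation import confusion_for_stratum, diagnostic_metrics, roc_auc
from .quality import QCThresholds
from .synthetic import CohortConfig, generate_cohort

#: exit code per stage family (CLI contract)
STAGE_EXIT_CODES = {
    "config": 2,
    "simulate": 10,
    "qc": 20,
    "augment": 30,
    "detect": 40,
    "features": 50,
    "train": 60,
    "predict": 61,
    "evaluate": 70,
}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and exit code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage
        self.exit_code = STAGE_EXIT_CODES.get(stage, 1)


@dataclass
class PipelineConfig:
    """Single-file configuration with CLI flag overrides."""

    n_slides: int = 1000
    seed: int = 17
    holdout_fraction: float = 0.2  # 4:1 train:validation split
    n_bins: int = DEFAULT_N_BINS
    n_trees: int = DEFAULT_N_TREES
    rf_seed: int = DEFAULT_RF_SEED
    dedup_iou: float = DEFAULT_DEDUP_IOU
    include_counts: bool = True
    include_glandular: bool = True
    patch_size_px: int = 1024
    stride_px: int = 768
    qc_blur_threshold: float = 0.5
    qc_incomplete_threshold: float = 0.3
    qc_low_cellularity_threshold: float = 0.5
    strata: List[str] = field(
        default_factory=lambda: [s.value for s in RiskStratum]
    )

    def __post_init__(self) -> None:
        if not (0.0 < self.holdout_fraction < 1.0):
            raise StageError("config", "holdout_fraction must be in (0, 1)")
        if self.stride_px > self.patch_size_px:
            raise StageError(
                "config", "stride_px must not exceed patch_size_px (gaps in coverage)"
            )

    @classmethod
    def from_yaml(cls, path: Union[str, Path], **overrides) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        payload.update({k: v for k, v in overrides.items() if v is not None})
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(payload) - known
        if unknown:
            raise StageError("config", f"unknown config keys: {sorted(unknown)}")
        return cls(**payload)

    def to_yaml(self, path: Union[str, Path]) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=True))

    def qc_thresholds(self) -> QCThresholds:
        return QCThresholds(
            blur=self.qc_blur_threshold,
            incomplete_scan=self.qc_incomplete_threshold,
            low_cellularity=self.qc_low_cellularity_threshold,
        )

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def train_validation_split(
    n: int, holdout_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic shuffled index split (train, holdout)."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_holdout = max(1, int(round(n * holdout_fraction)))
    return order[n_holdout:], order[:n_holdout]


def run_pipeline(cfg: PipelineConfig, out_dir: Union[str, Path]) -> Dict[str, Path]:
    """Run the full synthetic-cohort pipeline; returns artifact paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    artifacts: Dict[str, Path] = {}

    try:
        slides, truths = generate_cohort(
            CohortConfig(n_slides=cfg.n_slides, seed=cfg.seed)
        )
    except StageError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise StageError("simulate", str(exc)) from exc

    try:
        bins = default_bins(cfg.n_bins)
        features = [
            extract_features(ds, bins, cfg.include_counts, cfg.include_glandular)
            for ds in slides
        ]
        fmat = feature_matrix(features)
        fmat.insert(0, "slide_id", [ds.slide.slide_id for ds in slides])
        artifacts["features"] = out / "features.csv"
        fmat.to_csv(artifacts["features"], index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("features", str(exc)) from exc

    try:
        train_idx, hold_idx = train_validation_split(
            len(slides), cfg.holdout_fraction, cfg.seed
        )
        model = train_slide_classifier(
            [features[i] for i in train_idx],
            [truths[i] for i in train_idx],
            n_trees=cfg.n_trees,
            seed=cfg.rf_seed,
        )
        artifacts["model"] = out / "model.joblib"
        model.save(artifacts["model"])
    except Exception as exc:  # noqa: BLE001
        raise StageError("train", str(exc)) from exc

    try:
        predictions = [predict_slide_grade(model, features[i]) for i in hold_idx]
        hold_truth = [truths[i] for i in hold_idx]
        rows = []
        for i, pred in zip(hold_idx, predictions):
            row = {
                "slide_id": slides[i].slide.slide_id,
                "true_grade": truths[i].value,
                "predicted_grade": pred.grade.value,
                "abnormality_score": round(pred.abnormality_score, 9),
            }
            for g in SlideGrade:
                row[f"p_{g.value}"] = round(pred.probabilities[g], 9)
            rows.append(row)
        artifacts["predictions"] = out / "predictions.csv"
        pd.DataFrame(rows).to_csv(artifacts["predictions"], index=False)
    except Exception as exc:  # noqa: BLE001
        raise StageError("predict", str(exc)) from exc

    try:
        predicted_grades = [p.grade for p in predictions]
        report: Dict[str, dict] = {}
        for name in cfg.strata:
            stratum = RiskStratum(name)
            table = confusion_for_stratum(predicted_grades, hold_truth, stratum)
            rep = diagnostic_metrics(table)
            scores = [p.stratum_score(stratum) for p in predictions]
            labels = [t in stratum.slide_members for t in hold_truth]
            if any(labels) and not all(labels):
                rep.auc = roc_auc(scores, labels, seed=cfg.seed)
            report[stratum.value] = rep.to_dict()
        artifacts["report"] = out / "report.json"
        artifacts["report"].write_text(json.dumps(report, indent=2))
    except Exception as exc:  # noqa: BLE001
        raise StageError("evaluate", str(exc)) from exc

    artifacts["config"] = out / "config.yaml"
    cfg.to_yaml(artifacts["config"])
    artifacts["log"] = out / "run.log"
    artifacts["log"].write_text(
        json.dumps(
            {
                "cytoscreen_version": __version__,
                "python_version": platform.python_version(),
                "numpy_version": np.__version__,
                "config_hash": cfg.config_hash(),
                "seed": cfg.seed,
                "rf_seed": cfg.rf_seed,
                "n_slides": cfg.n_slides,
                "n_holdout": len(hold_idx),
                "oob_accuracy": model.oob_accuracy,
            },
            indent=2,
        )
    )
    return artifacts
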