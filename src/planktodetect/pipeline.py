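"""End-to-end orchestration: segment → detect → merge → describe → classify.

`run_train` composes candidate detection, ground-truth labelling, dictionary
building and the two-stage grid search into a fitted model; `run_detect`
applies a fitted model to new images and emits final detections with scores
and threshold decisions. All randomness funnels through the config's master
seed, so identical inputs reproduce identical outputs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import joblib
import numpy as np
import pandas as pd

from .candidates import Candidate, detect_candidates
from .classify import (GridSearchResult, TrainedModel, grid_search,
                       label_candidates)
from .io import GroundTruthBox, MicroscopyImage, PipelineConfig
from .merging import merge_colonies

logger = logging.getLogger(__name__)

DETECTION_COLUMNS = ["image_id", "candidate_id", "x_min", "y_min", "x_max",
                     "y_max", "area_px", "score", "is_phytoplankton"]


@dataclass
class Detection:
    image_id: str
    candidate: Candidate
    score: float
    is_phytoplankton: bool


def detect_and_merge(image: MicroscopyImage,
                     config: PipelineConfig) -> list[Candidate]:
    """Candidate detection followed by colony merging for one image."""
    cands = detect_candidates(image, config)
    merged = merge_colonies(cands, image, config)
    logger.info("stage=detect_merge image_id=%s candidates_in=%d candidates_out=%d",
                image.image_id, len(cands), len(merged))
    return merged


def run_detect(
    images: list[MicroscopyImage],
    config: PipelineConfig,
    model: TrainedModel,
) -> list[Detection]:
    """Full detection pass: all stages plus the model's operating threshold."""
    detections: list[Detection] = []
    for image in images:
        merged = detect_and_merge(image, config)
        if not merged:
            continue
        scores, decisions = model.predict(image, merged, config)
        for cand, s, keep in zip(merged, scores, decisions):
            detections.append(Detection(image.image_id, cand, float(s), bool(keep)))
    return detections


def run_train(
    images: list[MicroscopyImage],
    annotations: list[GroundTruthBox],
    config: PipelineConfig,
    mode: str = "colour",
    descriptor_grid: list[dict] | None = None,
    classifier_kind: str = "rf",
    classifier_grid: list[dict] | None = None,
    folds: int = 5,
    target_recall: float = 0.90,
) -> tuple[TrainedModel, GridSearchResult]:
    """Detect, label and grid-search over an annotated training set."""
    by_image: dict[str, list[GroundTruthBox]] = {}
    for g in annotations:
        by_image.setdefault(g.image_id, []).append(g)
    cands_per_image: list[list[Candidate]] = []
    labels_per_image: list[np.ndarray] = []
    for image in images:
        merged = detect_and_merge(image, config)
        labels = label_candidates(merged, by_image.get(image.image_id, []))
        cands_per_image.append(merged)
        labels_per_image.append(labels)
    total_pos = int(sum(l.sum() for l in labels_per_image))
    if total_pos == 0:
        raise ValueError("no positive candidates after labelling; cannot train")
    if descriptor_grid is None:
        descriptor_grid = default_descriptor_grid(mode)
    return grid_search(
        images, cands_per_image, labels_per_image, mode,
        descriptor_grid, classifier_kind, classifier_grid,
        config=config, folds=folds, target_recall=target_recall,
        seed=config.rng_seed,
    )


def default_descriptor_grid(mode: str) -> list[dict]:
    """Compact default grids keeping the search tractable at desk scale."""
    if mode == "colour":
        return [{"kc": k} for k in (10, 5)]
    if mode == "texture":
        return [{"kt": k, "fc": fc, "B": 1.5, "No": 4}
                for k in (10, 5) for fc in (0.25, 0.125)]
    if mode == "both":
        return [{"kc": k, "kt": k, "fc": fc, "B": 1.5, "No": 4}
                for k in (10, 5) for fc in (0.25,)]
    raise ValueError(f"unknown mode {mode!r}")


def detections_to_frame(detections: list[Detection]) -> pd.DataFrame:
    rows = []
    for d in detections:
        b = d.candidate.bbox
        rows.append({
            "image_id": d.image_id, "candidate_id": d.candidate.id,
            "x_min": b.x_min, "y_min": b.y_min, "x_max": b.x_max, "y_max": b.y_max,
            "area_px": d.candidate.area_px,
            "score": round(d.score, 12), "is_phytoplankton": int(d.is_phytoplankton),
        })
    return pd.DataFrame(rows, columns=DETECTION_COLUMNS)


def write_detections(path: str | Path, detections: list[Detection]) -> None:
    detections_to_frame(detections).to_csv(path, index=False)


def save_model(path: str | Path, model: TrainedModel,
               config: PipelineConfig) -> None:
    joblib.dump({"model": model, "config": config.to_dict(), "version": 1}, path)


def load_model(path: str | Path) -> tuple[TrainedModel, PipelineConfig]:
    bundle = joblib.load(path)
    return bundle["model"], PipelineConfig(**bundle["config"])
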