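"""Phytoplankton-vs-other classification of candidate detections.

Candidates surviving detection and merging are labelled against expert
ground truth (a candidate is a true specimen when its box covers at least
half of some phytoplankton ground-truth box) and classified from their BoVW
descriptors. Five classifier families are supported — random forest (rf),
RBF support vector machine (svm), k-nearest neighbours (knn), gradient
boosted trees (bt) and per-class Gaussian mixtures (gmm) — each exposing a
real-valued score where higher means more phytoplankton-like.

Model selection follows a two-stage cross-validated grid search whose
fitness is precision at a high recall target (0.90 by default): stage 1
selects the descriptor configuration (word count, and for texture the Gabor
centre frequency, bandwidth and orientation count) at default classifier
settings; stage 2 re-searches the classifier hyperparameters with the
stage-1 descriptor fixed. Visual dictionaries are rebuilt inside each
training fold so held-out folds never leak into dictionary building, and the
final dictionary is rebuilt on the whole training set.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.ensemble import GradientBoostingClassifier, RandomForestClassifier
from sklearn.mixture import GaussianMixture
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .candidates import Candidate
from .evaluate import precision_at_recall
from .features import (BoVWDictionary, build_dictionary, build_gabor_bank,
                       bovw_histogram, colour_rows, texture_responses,
                       texture_rows)
from .io import GroundTruthBox, MicroscopyImage, PipelineConfig

logger = logging.getLogger(__name__)

CLASSIFIER_KINDS = ("rf", "svm", "knn", "bt", "gmm")

DEFAULT_HYPERPARAMS: dict[str, dict] = {
    "rf": {"n_estimators": 100, "max_depth": None},
    "svm": {"C": 1.0, "gamma": "scale"},
    "knn": {"n_neighbors": 5},
    "bt": {"n_estimators": 100, "max_depth": 3, "learning_rate": 0.1},
    "gmm": {"n_components": 1},
}

DEFAULT_CLASSIFIER_GRIDS: dict[str, list[dict]] = {
    "rf": [{"n_estimators": n, "max_depth": d}
           for n in (50, 100) for d in (None, 8)],
    "svm": [{"C": c, "gamma": g} for c in (0.1, 1.0, 10.0) for g in ("scale", 1.0)],
    "knn": [{"n_neighbors": k} for k in (1, 3, 5, 9)],
    "bt": [{"n_estimators": n, "max_depth": d, "learning_rate": lr}
           for n in (50, 100) for d in (2, 3) for lr in (0.1,)],
    "gmm": [{"n_components": k} for k in (1, 2, 3)],
}


def label_candidates(cands: list[Candidate],
                     gts: list[GroundTruthBox]) -> np.ndarray:
    """Binary labels: 1 iff the candidate covers ≥50% of some phytoplankton
    ground-truth box's area."""
    labels = np.zeros(len(cands), dtype=int)
    phyto = [g for g in gts if g.label == "phytoplankton"]
    for i, c in enumerate(cands):
        for g in phyto:
            if c.bbox.intersection_area(g.box) >= 0.5 * g.box.area:
                labels[i] = 1
                break
    return labels


class CandidateClassifier(BaseEstimator):
    """Sklearn-style binary scorer over descriptor vectors.

    ``kind`` picks the family; ``hyperparams`` override that family's
    defaults. ``predict_scores`` returns a deterministic real score per
    sample, a monotone transform of the class-1 confidence. The gmm kind
    fits one Gaussian mixture per class and scores
    ``log p(x|1) − log p(x|0) + log(π₁/π₀)``.
    """

    def __init__(self, kind: str = "rf", hyperparams: dict | None = None,
                 seed: int = 0):
        self.kind = kind
        self.hyperparams = hyperparams
        self.seed = seed

    def _params(self) -> dict:
        if self.kind not in CLASSIFIER_KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        hp = dict(DEFAULT_HYPERPARAMS[self.kind])
        hp.update(self.hyperparams or {})
        return hp

    def fit(self, X: np.ndarray, y: np.ndarray) -> "CandidateClassifier":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y).astype(int)
        classes = np.unique(y)
        if len(classes) < 2:
            raise ValueError("training set must contain both classes")
        hp = self._params()
        if self.kind == "rf":
            self.model_ = RandomForestClassifier(random_state=self.seed, **hp).fit(X, y)
        elif self.kind == "svm":
            self.model_ = SVC(kernel="rbf", random_state=self.seed, **hp).fit(X, y)
        elif self.kind == "knn":
            hp = dict(hp)
            hp["n_neighbors"] = min(hp["n_neighbors"], len(y))
            self.model_ = KNeighborsClassifier(**hp).fit(X, y)
        elif self.kind == "bt":
            self.model_ = GradientBoostingClassifier(random_state=self.seed, **hp).fit(X, y)
        elif self.kind == "gmm":
            self.gmms_ = {}
            self.log_priors_ = {}
            for cls in (0, 1):
                rows = X[y == cls]
                n_comp = min(hp["n_components"], len(rows))
                gm = GaussianMixture(
                    n_components=n_comp, covariance_type="diag",
                    reg_covar=1e-6, random_state=self.seed,
                )
                gm.fit(rows)
                self.gmms_[cls] = gm
                self.log_priors_[cls] = np.log(len(rows) / len(y))
        self.n_features_in_ = X.shape[1]
        return self

    def predict_scores(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"descriptor dimension {X.shape[1]} does not match "
                f"training dimension {self.n_features_in_}"
            )
        if self.kind == "gmm":
            return (self.gmms_[1].score_samples(X) + self.log_priors_[1]
                    - self.gmms_[0].score_samples(X) - self.log_priors_[0])
        if self.kind in ("svm", "bt"):
            return np.asarray(self.model_.decision_function(X), dtype=float)
        proba = self.model_.predict_proba(X)
        idx = int(np.where(self.model_.classes_ == 1)[0][0])
        return proba[:, idx].astype(float)

    # alias so the estimator composes with sklearn model selection
    decision_function = predict_scores


def choose_operating_threshold(scores: np.ndarray, labels: np.ndarray,
                               target_recall: float) -> float:
    """Score cut-point with recall ≥ target and maximal precision.

    Predictions are positive when ``score >= threshold``. Among thresholds
    tied on precision, the highest (most conservative) is returned; the
    lowest observed score always achieves recall 1, so a solution exists for
    any target ≤ 1.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n_pos = int(labels.sum())
    if n_pos == 0 or n_pos == len(labels):
        raise ValueError("both classes must be present")
    best: tuple[float, float] | None = None  # (precision, threshold)
    for t in np.unique(scores)[::-1]:
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        recall = tp / n_pos
        if recall < target_recall:
            continue
        precision = tp / int(pred.sum())
        if best is None or precision > best[0]:
            best = (precision, float(t))
    assert best is not None
    return best[1]


# ---------------------------------------------------------------------------
# Grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSearchResult:
    best_config: dict
    fitness: float
    stage1_table: list[dict] = field(default_factory=list)
    stage2_table: list[dict] = field(default_factory=list)


@dataclass
class TrainedModel:
    kind: str
    mode: str
    hyperparams: dict
    descriptor_params: dict
    dicts: dict[str, BoVWDictionary]
    classifier: CandidateClassifier
    operating_threshold: float
    seed: int

    def describe(self, image: MicroscopyImage, cands: list[Candidate],
                 config: PipelineConfig) -> np.ndarray:
        """Descriptor matrix for a list of candidates of one image."""
        if not cands:
            return np.empty((0, sum(d.k for d in self.dicts.values())))
        frac = config.bbox_growth_frac
        parts = []
        if self.mode in ("colour", "both"):
            parts.append(np.array([
                bovw_histogram(colour_rows(image, c, frac), self.dicts["colour"])
                for c in cands]))
        if self.mode in ("texture", "both"):
            bank = build_gabor_bank(self.descriptor_params["fc"],
                                    self.descriptor_params["B"],
                                    self.descriptor_params["No"])
            resp = texture_responses(image, bank)
            parts.append(np.array([
                bovw_histogram(texture_rows(resp, c, frac), self.dicts["texture"])
                for c in cands]))
        X = np.hstack(parts)
        if self.mode == "both":
            X = X / X.sum(axis=1, keepdims=True)
        return X

    def predict(self, image: MicroscopyImage, cands: list[Candidate],
                config: PipelineConfig) -> tuple[np.ndarray, np.ndarray]:
        """(scores, decisions) for the candidates of one image."""
        X = self.describe(image, cands, config)
        if len(X) == 0:
            return np.empty(0), np.empty(0, dtype=bool)
        scores = self.classifier.predict_scores(X)
        return scores, scores >= self.operating_threshold


class _DescriptorCache:
    """Per-candidate base-feature rows, cached across grid configurations."""

    def __init__(self, images: list[MicroscopyImage],
                 cands_per_image: list[list[Candidate]],
                 growth_frac: float):
        self.images = images
        self.cands_per_image = cands_per_image
        self.growth_frac = growth_frac
        self.flat: list[tuple[int, Candidate]] = [
            (i, c) for i, cl in enumerate(cands_per_image) for c in cl
        ]
        self._colour: list[np.ndarray] | None = None
        self._texture: dict[tuple, list[np.ndarray]] = {}

    def colour(self) -> list[np.ndarray]:
        if self._colour is None:
            self._colour = [
                colour_rows(self.images[i], c, self.growth_frac)
                for i, c in self.flat
            ]
        return self._colour

    def texture(self, fc: float, B: float, No: int) -> list[np.ndarray]:
        key = (fc, B, No)
        if key not in self._texture:
            bank = build_gabor_bank(fc, B, No)
            rows: list[np.ndarray] = []
            for i, image in enumerate(self.images):
                if not self.cands_per_image[i]:
                    continue
                resp = texture_responses(image, bank)
                for c in self.cands_per_image[i]:
                    rows.append(texture_rows(resp, c, self.growth_frac))
            self._texture[key] = rows
        return self._texture[key]


def _histograms(mode: str, desc: dict, cache: _DescriptorCache,
                train_idx: np.ndarray, seed: int
                ) -> tuple[np.ndarray, dict[str, BoVWDictionary]]:
    """Fit dictionaries on the training rows only; describe every candidate."""
    parts = []
    dicts: dict[str, BoVWDictionary] = {}
    if mode in ("colour", "both"):
        rows = cache.colour()
        pool = np.vstack([rows[i] for i in train_idx])
        dicts["colour"] = build_dictionary(pool, desc["kc"], seed, mode="colour")
        parts.append(np.array([bovw_histogram(r, dicts["colour"]) for r in rows]))
    if mode in ("texture", "both"):
        rows = cache.texture(desc["fc"], desc["B"], desc["No"])
        pool = np.vstack([rows[i] for i in train_idx])
        dicts["texture"] = build_dictionary(pool, desc["kt"], seed, mode="texture")
        parts.append(np.array([bovw_histogram(r, dicts["texture"]) for r in rows]))
    X = np.hstack(parts)
    if mode == "both":
        X = X / X.sum(axis=1, keepdims=True)
    return X, dicts


def _cv_fitness(mode: str, desc: dict, hyperparams: dict, kind: str,
                cache: _DescriptorCache, labels: np.ndarray,
                folds: int, target_recall: float, seed: int) -> float | None:
    """Mean held-out precision@recall across stratified folds; None if the
    configuration is infeasible."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_scores = []
    for train_idx, test_idx in skf.split(np.zeros(len(labels)), labels):
        if labels[test_idx].sum() == 0 or labels[train_idx].sum() in (0, len(train_idx)):
            logger.warning("fold without both classes: excluded from fitness")
            continue
        try:
            X, _ = _histograms(mode, desc, cache, train_idx, seed)
        except ValueError as exc:
            logger.warning("skipping config %s: %s", desc, exc)
            return None
        clf = CandidateClassifier(kind=kind, hyperparams=hyperparams, seed=seed)
        clf.fit(X[train_idx], labels[train_idx])
        scores = clf.predict_scores(X[test_idx])
        if len(np.unique(labels[test_idx])) < 2:
            continue
        fold_scores.append(
            precision_at_recall(scores, labels[test_idx], target_recall))
    if not fold_scores:
        return None
    return float(np.mean(fold_scores))


def grid_search(
    images: list[MicroscopyImage],
    cands_per_image: list[list[Candidate]],
    labels_per_image: list[np.ndarray],
    mode: str,
    descriptor_grid: list[dict],
    classifier_kind: str,
    classifier_grid: list[dict] | None = None,
    config: PipelineConfig | None = None,
    folds: int = 5,
    target_recall: float = 0.90,
    seed: int = 0,
) -> tuple[TrainedModel, GridSearchResult]:
    """Two-stage cross-validated grid search; returns the final fitted model.

    Stage 1 ranks descriptor configurations (at the classifier family's
    default hyperparameters), stage 2 ranks classifier hyperparameters at the
    stage-1 winner; ties break to the earliest entry in grid order. The
    returned model carries dictionaries rebuilt on the whole training set, a
    classifier refitted on all data, and an operating threshold chosen for
    ``target_recall`` on the training scores.
    """
    if not descriptor_grid:
        raise ValueError("descriptor grid must be non-empty")
    if folds < 2:
        raise ValueError("need folds >= 2")
    config = config or PipelineConfig()
    classifier_grid = classifier_grid or DEFAULT_CLASSIFIER_GRIDS[classifier_kind]
    labels = np.concatenate([np.asarray(l, int) for l in labels_per_image]) \
        if labels_per_image else np.empty(0, int)
    if labels.sum() == 0 or labels.sum() == len(labels):
        raise ValueError("training data must contain both classes")
    cache = _DescriptorCache(images, cands_per_image, config.bbox_growth_frac)

    stage1 = []
    best_desc, best_desc_fit = None, -1.0
    for desc in descriptor_grid:
        fit = _cv_fitness(mode, desc, DEFAULT_HYPERPARAMS[classifier_kind],
                          classifier_kind, cache, labels, folds,
                          target_recall, seed)
        stage1.append({"descriptor": dict(desc), "fitness": fit})
        if fit is not None and fit > best_desc_fit:
            best_desc, best_desc_fit = desc, fit
    if best_desc is None:
        raise ValueError("no feasible descriptor configuration in the grid")

    stage2 = []
    best_hp, best_fit = None, -1.0
    for hp in classifier_grid:
        fit = _cv_fitness(mode, best_desc, hp, classifier_kind, cache, labels,
                          folds, target_recall, seed)
        stage2.append({"hyperparams": dict(hp), "fitness": fit})
        if fit is not None and fit > best_fit:
            best_hp, best_fit = hp, fit
    if best_hp is None:
        raise ValueError("no feasible classifier configuration in the grid")

    all_idx = np.arange(len(labels))
    X, dicts = _histograms(mode, best_desc, cache, all_idx, seed)
    clf = CandidateClassifier(kind=classifier_kind, hyperparams=best_hp,
                              seed=seed).fit(X, labels)
    train_scores = clf.predict_scores(X)
    threshold = choose_operating_threshold(train_scores, labels, target_recall)
    model = TrainedModel(
        kind=classifier_kind, mode=mode, hyperparams=dict(best_hp),
        descriptor_params=dict(best_desc), dicts=dicts, classifier=clf,
        operating_threshold=threshold, seed=seed,
    )
    result = GridSearchResult(
        best_config={"descriptor": dict(best_desc), "hyperparams": dict(best_hp)},
        fitness=best_fit, stage1_table=stage1, stage2_table=stage2,
    )
    return model, result
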