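import math

import numpy as np
import pytest

from _oracles import best_threshold_scan
from planktodetect.candidates import Candidate
from planktodetect.classify import (CLASSIFIER_KINDS, CandidateClassifier,
                                    choose_operating_threshold, grid_search,
                                    label_candidates)
from planktodetect.io import BoundingBox, GroundTruthBox, MicroscopyImage, PipelineConfig


def gt(x0, y0, x1, y1, label="phytoplankton", image_id="img"):
    return GroundTruthBox(image_id, BoundingBox(x0, y0, x1, y1), label)


def det_candidate(x0, y0, x1, y1, cid=0):
    mask = np.ones((y1 - y0, x1 - x0), bool)
    return Candidate(cid, np.empty((0, 2)), mask, BoundingBox(x0, y0, x1, y1),
                     ((y0 + y1) / 2, (x0 + x1) / 2), float(mask.sum()),
                     np.zeros(3))


def separable_set(n=40, d=3, seed=0):
    rng = np.random.default_rng(seed)
    X0 = rng.normal(0.0, 0.4, (n // 2, d))
    X1 = rng.normal(4.0, 0.4, (n - n // 2, d))
    X = np.vstack([X0, X1])
    y = np.array([0] * (n // 2) + [1] * (n - n // 2))
    perm = rng.permutation(n)
    return X[perm], y[perm]


class TestLabelCandidates:
    def test_identical_box_is_positive(self):
        c = det_candidate(10, 10, 30, 30)
        assert label_candidates([c], [gt(10, 10, 30, 30)]).tolist() == [1]

    def test_forty_percent_overlap_is_negative(self):
        # detection covers 40% of the GT box's area
        c = det_candidate(0, 0, 10, 8)   # ∩ = 10×8 = 80 of GT 10×20 = 200
        assert label_candidates([c], [gt(0, 0, 10, 20)]).tolist() == [0]

    def test_half_overlap_inclusive(self):
        c = det_candidate(0, 0, 10, 10)  # ∩ = 100 = 0.5 × 200
        assert label_candidates([c], [gt(0, 0, 10, 20)]).tolist() == [1]

    def test_no_ground_truth_all_negative(self):
        cands = [det_candidate(0, 0, 5, 5), det_candidate(10, 10, 20, 20, 1)]
        assert label_candidates(cands, []).tolist() == [0, 0]

    def test_other_label_does_not_count(self):
        c = det_candidate(10, 10, 30, 30)
        assert label_candidates([c], [gt(10, 10, 30, 30, label="other")]).tolist() == [0]


class TestCandidateClassifier:
    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_separable_training_set_perfect_pr(self, kind):
        """On a linearly separable toy set every family reaches precision 1 at
        recall 1 on its own training data."""
        from planktodetect.evaluate import precision_at_recall
        X, y = separable_set()
        clf = CandidateClassifier(kind=kind, seed=0).fit(X, y)
        scores = clf.predict_scores(X)
        assert precision_at_recall(scores, y, 1.0) == 1.0

    @pytest.mark.parametrize("kind", CLASSIFIER_KINDS)
    def test_determinism(self, kind):
        X, y = separable_set(seed=3)
        s1 = CandidateClassifier(kind=kind, seed=7).fit(X, y).predict_scores(X)
        s2 = CandidateClassifier(kind=kind, seed=7).fit(X, y).predict_scores(X)
        np.testing.assert_array_equal(s1, s2)

    def test_single_class_rejected(self):
        X = np.zeros((10, 2))
        with pytest.raises(ValueError):
            CandidateClassifier().fit(X, np.ones(10))

    def test_dimension_mismatch_rejected(self):
        X, y = separable_set()
        clf = CandidateClassifier().fit(X, y)
        with pytest.raises(ValueError):
            clf.predict_scores(np.zeros((3, 5)))

    def test_gmm_matches_gaussian_likelihood_ratio(self):
        """The gmm score sign equals the closed-form log likelihood ratio of
        per-class normal fits (sample mean, MLE variance, equal priors)."""
        rng = np.random.default_rng(0)
        x0 = rng.normal(0.0, 1.0, 60)
        x1 = rng.normal(6.0, 1.0, 60)
        X = np.concatenate([x0, x1])[:, None]
        y = np.array([0] * 60 + [1] * 60)
        clf = CandidateClassifier(kind="gmm", seed=0).fit(X, y)

        def logpdf(x, data):
            mu, var = data.mean(), data.var()
            return -0.5 * math.log(2 * math.pi * var) - (x - mu) ** 2 / (2 * var)

        grid = np.linspace(-3, 9, 50)
        scores = clf.predict_scores(grid[:, None])
        oracle = np.array([logpdf(v, x1) - logpdf(v, x0) for v in grid])
        assert (np.sign(scores) == np.sign(oracle)).all()
        np.testing.assert_allclose(scores, oracle, atol=1e-3)


class TestOperatingThreshold:
    def test_perfect_separation(self):
        scores = np.array([0.9, 0.8, 0.2, 0.1])
        labels = np.array([1, 1, 0, 0])
        t = choose_operating_threshold(scores, labels, 0.9)
        pred = scores >= t
        assert pred.tolist() == [True, True, False, False]

    def test_worked_example(self):
        # target recall 0.9 forces all 3 positives in: precision 3/4
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 1, 0, 1])
        t = choose_operating_threshold(scores, labels, 0.9)
        assert t == 0.6
        pred = scores >= t
        tp = int(np.sum(pred & (labels == 1)))
        assert tp / pred.sum() == pytest.approx(3 / 4)

    def test_all_equal_scores_give_prevalence(self):
        scores = np.zeros(10)
        labels = np.array([1] * 3 + [0] * 7)
        t = choose_operating_threshold(scores, labels, 0.9)
        pred = scores >= t
        assert pred.all()

    def test_matches_brute_force_scan(self):
        """Equals the all-threshold scan on 200 random score/label sets."""
        rng = np.random.default_rng(99)
        for _ in range(200):
            n = int(rng.integers(4, 51))
            scores = np.round(rng.normal(0, 1, n), 1)  # ties likely
            labels = rng.integers(0, 2, n)
            if labels.sum() in (0, n):
                continue
            target = float(rng.choice([0.5, 0.9, 0.95, 1.0]))
            t = choose_operating_threshold(scores, labels, target)
            t_oracle, p_oracle = best_threshold_scan(scores, labels, target)
            assert t == t_oracle
            pred = scores >= t
            tp = int(np.sum(pred & (labels == 1)))
            assert tp / pred.sum() == pytest.approx(p_oracle)


def make_toy_images(seed=0, n_images=4, separable_colour=True):
    """Tiny images with one dark candidate each, colour-separable by class."""
    rng = np.random.default_rng(seed)
    images, cands, labels = [], [], []
    for i in range(n_images * 6):
        pixels = np.full((48, 48, 3), 230, np.uint8)
        positive = i % 2 == 0
        colour = (60, 120, 60) if positive else (140, 60, 140)
        pixels[18:30, 18:30] = colour
        img = MicroscopyImage(pixels + rng.integers(0, 3, pixels.shape,
                                                    dtype=np.uint8),
                              1.5, f"toy_{i}")
        c = det_candidate(18, 18, 30, 30, cid=0)
        images.append(img)
        cands.append([c])
        labels.append(np.array([int(positive)]))
    return images, cands, labels


class TestGridSearch:
    def test_single_config_returned(self):
        images, cands, labels = make_toy_images()
        model, result = grid_search(
            images, cands, labels, "colour", [{"kc": 3}], "rf",
            classifier_grid=[{"n_estimators": 20, "max_depth": None}],
            folds=3, seed=0)
        assert result.best_config["descriptor"] == {"kc": 3}
        assert 0 <= result.fitness <= 1
        assert model.dicts["colour"].k == 3

    def test_determinism(self):
        images, cands, labels = make_toy_images()
        out = []
        for _ in range(2):
            model, result = grid_search(
                images, cands, labels, "colour", [{"kc": 3}, {"kc": 2}], "rf",
                classifier_grid=[{"n_estimators": 20, "max_depth": None}],
                folds=3, seed=5)
            out.append((result.best_config["descriptor"]["kc"],
                        result.fitness, model.operating_threshold,
                        model.dicts["colour"].centroids.tobytes()))
        assert out[0] == out[1]

    def test_infeasible_k_skipped(self):
        images, cands, labels = make_toy_images()
        model, result = grid_search(
            images, cands, labels, "colour", [{"kc": 10 ** 6}, {"kc": 3}], "rf",
            classifier_grid=[{"n_estimators": 20, "max_depth": None}],
            folds=3, seed=0)
        assert result.best_config["descriptor"] == {"kc": 3}
        assert result.stage1_table[0]["fitness"] is None

    def test_fold_assignment_depends_only_on_seed_and_labels(self):
        from sklearn.model_selection import StratifiedKFold
        labels = np.array([0, 1] * 10)
        a = [t.tolist() for _, t in
             StratifiedKFold(5, shuffle=True, random_state=3).split(
                 np.zeros(20), labels)]
        b = [t.tolist() for _, t in
             StratifiedKFold(5, shuffle=True, random_state=3).split(
                 np.ones(20), labels)]
        assert a == b

    def test_single_class_rejected(self):
        images, cands, labels = make_toy_images()
        labels = [np.zeros_like(l) for l in labels]
        with pytest.raises(ValueError):
            grid_search(images, cands, labels, "colour", [{"kc": 3}], "rf",
                        folds=3, seed=0)
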