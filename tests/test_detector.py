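"""Tests for the contrast pre-filter, training, bootstrap and detection."""

from dataclasses import replace

import numpy as np
import pytest

from wildcount.detector import (
    DetectorConfig,
    PixelClassifier,
    TrainingSet,
    bootstrap_train,
    detect,
    harvest_training_set,
    local_contrast_mask,
    to_grayscale,
    train,
)
from wildcount.evaluate import match_detections
from wildcount.exceptions import (
    InvalidInputError,
    InvalidModelError,
    InvalidParameterError,
)
from wildcount.fourierhog import FeatureConfig, FourierHOG
from wildcount.synthetic import generate_scene

from oracles import flood_fill_components, naive_windowed_std


class TestLocalContrastMask:
    def test_constant_image_all_false(self):
        assert not local_contrast_mask(np.full((20, 20), 0.4), 5, 0.01).any()

    def test_blob_on_flat_background_localizes_contrast(self):
        image = np.full((40, 40), 0.6)
        image[18:23, 18:23] = 0.1
        mask = local_contrast_mask(image, 5, 0.05)
        assert mask.any()
        ys, xs = np.nonzero(mask)
        assert ys.min() >= 14 and ys.max() <= 26
        assert xs.min() >= 14 and xs.max() <= 26

    def test_matches_windowed_std_oracle(self):
        rng = np.random.default_rng(2)
        image = rng.random((12, 12))
        std = naive_windowed_std(image, 5)
        mask = local_contrast_mask(image, 5, 0.2)
        assert np.array_equal(mask, std > 0.2)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(3)
        image = rng.random((30, 30))
        counts = [
            local_contrast_mask(image, 5, t).sum() for t in (0.05, 0.1, 0.2, 0.3)
        ]
        assert np.all(np.diff(counts) <= 0)

    def test_rejects_even_window(self):
        with pytest.raises(InvalidParameterError):
            local_contrast_mask(np.zeros((10, 10)), 4, 0.1)


class TestTraining:
    def test_separable_toy_problem_reaches_perfect_accuracy(self):
        rng = np.random.default_rng(4)
        X = np.vstack([rng.normal(0, 0.3, (50, 2)), rng.normal(3, 0.3, (50, 2))])
        y = np.repeat([0, 1], 50)
        clf = train(TrainingSet(X=X, y=y), feature_config=FeatureConfig())
        assert clf.metadata["training_accuracy"] == 1.0

    def test_rejects_single_class(self):
        X = np.random.default_rng(5).normal(size=(10, 3))
        with pytest.raises(InvalidInputError):
            train(TrainingSet(X=X, y=np.ones(10, dtype=int)))

    def test_permuted_labels_give_chance_heldout_accuracy(self):
        # destroying the label signal must collapse held-out accuracy to ~0.5
        rng = np.random.default_rng(6)
        X = np.vstack([rng.normal(0, 0.5, (150, 4)), rng.normal(2, 0.5, (150, 4))])
        y = rng.permutation(np.repeat([0, 1], 150))
        clf = train(
            TrainingSet(X=X[:200], y=y[:200]),
            feature_config=FeatureConfig(),
            config=DetectorConfig(seed=6),
        )
        heldout = clf.predict(X[200:])
        accuracy = np.mean(heldout == y[200:])
        assert 0.3 < accuracy < 0.7

    def test_training_is_deterministic(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(60, 5))
        y = (X[:, 0] > 0).astype(int)
        c1 = train(TrainingSet(X=X, y=y), config=DetectorConfig(seed=1))
        c2 = train(TrainingSet(X=X, y=y), config=DetectorConfig(seed=1))
        probe = rng.normal(size=(20, 5))
        assert np.array_equal(c1.scores(probe), c2.scores(probe))

    def test_synthetic_blob_descriptors_classify_well(
        self, small_hog, small_scene_config, small_classifier
    ):
        # held-out scenes the fixture classifier never saw
        images, truths = [], []
        for i in range(4):
            image, truth = generate_scene(replace(small_scene_config, seed=900 + i))
            images.append(image)
            truths.append(truth[["x", "y"]].to_numpy())
        heldout = harvest_training_set(
            images, truths, small_hog, n_negative_per_image=6,
            rng=np.random.default_rng(99),
        )
        accuracy = np.mean(small_classifier.predict(heldout.X) == heldout.y)
        assert accuracy > 0.9


class TestModelRoundTrip:
    def test_save_load_preserves_predictions(self, small_classifier, tmp_path):
        rng = np.random.default_rng(8)
        probe = rng.normal(size=(10, small_classifier.n_features))
        path = small_classifier.save(tmp_path / "model.joblib")
        loaded = PixelClassifier.load(path)
        assert np.array_equal(loaded.scores(probe), small_classifier.scores(probe))
        assert loaded.feature_config == small_classifier.feature_config

    def test_load_rejects_foreign_file(self, tmp_path):
        import joblib

        path = tmp_path / "junk.joblib"
        joblib.dump({"something": 1}, path)
        with pytest.raises(InvalidModelError):
            PixelClassifier.load(path)

    def test_descriptor_length_mismatch_is_rejected(self, small_classifier):
        with pytest.raises(InvalidModelError):
            small_classifier.scores(np.zeros((3, small_classifier.n_features + 1)))


class TestDetect:
    def test_blank_background_counts_zero(
        self, small_classifier, small_detector_config, small_hog
    ):
        image = np.full((96, 96), 0.55)
        result = detect(image, small_classifier, small_detector_config,
                        extractor=small_hog)
        assert result.count == 0
        assert not result.mask.any()

    def test_count_equals_component_count(
        self, small_classifier, small_detector_config, small_hog, small_scene_config
    ):
        image, _ = generate_scene(replace(small_scene_config, seed=300))
        result = detect(image, small_classifier, small_detector_config,
                        extractor=small_hog)
        assert result.count == len(result.components)
        assert result.count == flood_fill_components(result.mask)

    def test_recovers_planted_blobs(
        self, small_classifier, small_detector_config, small_hog, small_scene_config
    ):
        tp = fp = fn = 0
        for i in range(5):
            image, truth = generate_scene(replace(small_scene_config, seed=400 + i))
            result = detect(image, small_classifier, small_detector_config,
                            extractor=small_hog)
            c = match_detections(
                [(d.x, d.y) for d in result.components],
                truth[["x", "y"]].to_numpy(),
                radius=small_hog.config.window / 2,
            )
            tp, fp, fn = tp + c.tp, fp + c.fp, fn + c.fn
        assert tp / (tp + fn) > 0.8
        assert tp / (tp + fp) > 0.8

    def test_detection_is_deterministic(
        self, small_classifier, small_detector_config, small_hog, small_scene_config
    ):
        image, _ = generate_scene(replace(small_scene_config, seed=500))
        r1 = detect(image, small_classifier, small_detector_config, extractor=small_hog)
        r2 = detect(image, small_classifier, small_detector_config, extractor=small_hog)
        assert r1.count == r2.count
        assert np.array_equal(r1.mask, r2.mask)
        assert [(d.x, d.y, d.area, d.score) for d in r1.components] == [
            (d.x, d.y, d.area, d.score) for d in r2.components
        ]

    def test_extractor_config_mismatch_is_rejected(self, small_classifier):
        wrong = FourierHOG(FeatureConfig(window=12, m_max=2, k_max=2, n_rings=2))
        with pytest.raises(InvalidModelError):
            detect(np.full((40, 40), 0.5), small_classifier, extractor=wrong)

    def test_min_area_filters_small_components(
        self, small_classifier, small_detector_config, small_hog, small_scene_config
    ):
        image, _ = generate_scene(replace(small_scene_config, seed=600))
        loose = detect(image, small_classifier, small_detector_config,
                       extractor=small_hog)
        strict_cfg = replace(small_detector_config, min_area=10**6)
        strict = detect(image, small_classifier, strict_cfg, extractor=small_hog)
        assert strict.count == 0
        assert loose.count >= strict.count


class TestGrayscale:
    def test_luma_weights(self):
        rgb = np.zeros((2, 2, 3))
        rgb[..., 0] = 1.0
        assert np.allclose(to_grayscale(rgb), 0.299)

    def test_passthrough_for_gray(self):
        image = np.random.default_rng(0).random((4, 4))
        assert to_grayscale(image) is image or np.array_equal(
            to_grayscale(image), image
        )


class TestBootstrap:
    def test_accept_all_appends_every_detection(
        self, small_hog, small_detector_config, small_scene_config, small_classifier
    ):
        initial = _tiny_training_set(small_hog, small_scene_config)
        images = [
            generate_scene(replace(small_scene_config, seed=700 + i))[0]
            for i in range(2)
        ]
        n_detections = []

        def accept_all(i, result):
            n_detections.append(len(result.components))
            return [True] * len(result.components)

        grown = bootstrap_train(
            initial, images, accept_all, small_hog, config=small_detector_config
        )
        assert len(grown) == len(initial) + sum(n_detections)
        assert sum(n_detections) > 0

    def test_reject_all_appends_only_negatives(
        self, small_hog, small_detector_config, small_scene_config
    ):
        initial = _tiny_training_set(small_hog, small_scene_config)
        images = [generate_scene(replace(small_scene_config, seed=710))[0]]
        grown = bootstrap_train(
            initial,
            images,
            lambda i, r: [False] * len(r.components),
            small_hog,
            config=small_detector_config,
        )
        assert (grown.y[: len(initial)] == initial.y).all()
        assert (grown.y[len(initial):] == 0).all()
        assert int(grown.y.sum()) == int(initial.y.sum())

    def test_callback_failure_preserves_partial_set(
        self, small_hog, small_detector_config, small_scene_config, tmp_path
    ):
        import joblib

        initial = _tiny_training_set(small_hog, small_scene_config)
        images = [
            generate_scene(replace(small_scene_config, seed=720 + i))[0]
            for i in range(2)
        ]

        def explode(i, result):
            if i == 1:
                raise RuntimeError("annotator went home")
            return [True] * len(result.components)

        checkpoint = tmp_path / "partial.joblib"
        with pytest.raises(RuntimeError):
            bootstrap_train(
                initial, images, explode, small_hog,
                config=small_detector_config, checkpoint_path=checkpoint,
            )
        saved = joblib.load(checkpoint)
        assert len(saved) >= len(initial)

    def test_ground_truth_callback_reduces_false_positives(
        self, small_hog, small_detector_config, small_scene_config
    ):
        # detections confirmed/corrected against synthetic ground truth must
        # not increase the false-positive count on a held-out scene
        initial = _tiny_training_set(small_hog, small_scene_config)
        scenes = [
            generate_scene(replace(small_scene_config, seed=730 + i))
            for i in range(5)
        ]
        images = [s[0] for s in scenes]
        truths = [s[1][["x", "y"]].to_numpy() for s in scenes]

        def oracle(i, result):
            c = truths[i]
            out = []
            for d in result.components:
                dist = np.hypot(c[:, 0] - d.x, c[:, 1] - d.y).min() if len(c) else np.inf
                out.append(bool(dist <= small_hog.config.window / 2))
            return out

        grown = bootstrap_train(
            initial, images, oracle, small_hog, config=small_detector_config
        )
        before = train(initial, feature_config=small_hog.config,
                       config=small_detector_config)
        after = train(grown, feature_config=small_hog.config,
                      config=small_detector_config)
        heldout, heldout_truth = generate_scene(
            replace(small_scene_config, seed=799)
        )
        fp_counts = []
        for clf in (before, after):
            result = detect(heldout, clf, small_detector_config, extractor=small_hog)
            c = match_detections(
                [(d.x, d.y) for d in result.components],
                heldout_truth[["x", "y"]].to_numpy(),
                radius=small_hog.config.window / 2,
            )
            fp_counts.append(c.fp)
        assert fp_counts[1] <= fp_counts[0]


def _tiny_training_set(hog, scene_config):
    images, truths = [], []
    for i in range(3):
        image, truth = generate_scene(replace(scene_config, seed=800 + i))
        images.append(image)
        truths.append(truth[["x", "y"]].to_numpy())
    return harvest_training_set(
        images, truths, hog, n_negative_per_image=6,
        rng=np.random.default_rng(17),
    )
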