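"""Boosted per-pixel classification and object counting.

The pipeline mirrors a classical sliding-window survey counter:

1. convert to grayscale and discard uniform regions with a local-contrast
   pre-filter (windowed standard deviation above a threshold);
2. treat every remaining pixel as a candidate object centre, extract its
   rotation-invariant Fourier HOG descriptor and classify it with an
   AdaBoost ensemble of shallow decision trees;
3. group contiguous (8-connected) positive pixels into components — each
   component is counted as one animal.

Training descriptors come from annotated object centroids (positives) and
from background locations at least one window-diameter away from any
annotation (negatives).  An optional bootstrap round runs the detector on
further images and feeds corrected detections back into the training set,
mimicking the iterative check-and-correct protocol used in practice.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable, Sequence

import joblib
import numpy as np
from scipy import ndimage
from sklearn.ensemble import AdaBoostClassifier
from sklearn.tree import DecisionTreeClassifier

from .exceptions import (
    InvalidInputError,
    InvalidModelError,
    InvalidParameterError,
)
from .fourierhog import FeatureConfig, FourierHOG

logger = logging.getLogger(__name__)

__all__ = [
    "DetectorConfig",
    "TrainingSet",
    "PixelClassifier",
    "Detection",
    "DetectionResult",
    "local_contrast_mask",
    "train",
    "bootstrap_train",
    "detect",
    "harvest_training_set",
    "to_grayscale",
]

MODEL_FORMAT = "wildcount-model"
MODEL_VERSION = 1

#: ITU-R BT.601 luma weights used for grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Collapse an RGB image to luma; pass 2-d images through unchanged."""
    image = np.asarray(image, dtype=float)
    if image.ndim == 2:
        return image
    if image.ndim == 3 and image.shape[2] in (3, 4):
        r, g, b = image[..., 0], image[..., 1], image[..., 2]
        return LUMA_WEIGHTS[0] * r + LUMA_WEIGHTS[1] * g + LUMA_WEIGHTS[2] * b
    raise InvalidInputError(f"cannot interpret image of shape {image.shape}")


@dataclass(frozen=True)
class DetectorConfig:
    """Scan/classify/group parameters.

    ``contrast_window`` (odd, pixels) and ``contrast_threshold`` (intensity
    std-dev units) control the uniform-region pre-filter; ``stride``
    subsamples the scan grid; ``min_area`` (pixels) drops components
    smaller than the given size (0 = keep all); ``score_threshold`` is the
    positive-class probability cut.  Boosting hyper-parameters follow:
    number of rounds, tree depth, learning rate, RNG seed.
    """

    contrast_window: int = 9
    contrast_threshold: float = 0.05
    stride: int = 1
    min_area: int = 0
    score_threshold: float = 0.5
    n_estimators: int = 100
    max_depth: int = 2
    learning_rate: float = 1.0
    seed: int = 0

    def to_dict(self) -> dict:
        return {
            "contrast_window": self.contrast_window,
            "contrast_threshold": self.contrast_threshold,
            "stride": self.stride,
            "min_area": self.min_area,
            "score_threshold": self.score_threshold,
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "learning_rate": self.learning_rate,
            "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d) -> "DetectorConfig":
        return cls(
            contrast_window=int(d["contrast_window"]),
            contrast_threshold=float(d["contrast_threshold"]),
            stride=int(d["stride"]),
            min_area=int(d["min_area"]),
            score_threshold=float(d["score_threshold"]),
            n_estimators=int(d["n_estimators"]),
            max_depth=int(d["max_depth"]),
            learning_rate=float(d["learning_rate"]),
            seed=int(d["seed"]),
        )


@dataclass
class TrainingSet:
    """Labelled descriptor matrix: X (n, d), y in {0, 1}, provenance strings."""

    X: np.ndarray
    y: np.ndarray
    source: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y, dtype=int)
        if self.X.ndim != 2 or self.X.shape[0] != self.y.shape[0]:
            raise InvalidInputError("X must be (n, d) with one label per row")
        if not self.source:
            self.source = ["unknown"] * len(self.y)

    def __len__(self) -> int:
        return len(self.y)

    def extend(self, X: np.ndarray, y: np.ndarray, source: Iterable[str]) -> "TrainingSet":
        return TrainingSet(
            X=np.vstack([self.X, np.asarray(X, dtype=float)]),
            y=np.concatenate([self.y, np.asarray(y, dtype=int)]),
            source=list(self.source) + list(source),
        )


@dataclass
class Detection:
    """One detected object: centroid (x, y), pixel area, classifier score."""

    x: float
    y: float
    area: int
    score: float


@dataclass
class DetectionResult:
    """Per-image output: positive-pixel mask, grouped detections, count."""

    mask: np.ndarray
    components: list[Detection]
    count: int


class PixelClassifier:
    """Trained AdaBoost ensemble plus the feature configuration it expects."""

    def __init__(
        self,
        model: AdaBoostClassifier,
        feature_config: FeatureConfig,
        metadata: dict | None = None,
    ) -> None:
        self.model = model
        self.feature_config = feature_config
        self.metadata = metadata or {}

    @property
    def n_features(self) -> int:
        return int(self.model.n_features_in_)

    def scores(self, X: np.ndarray) -> np.ndarray:
        """Positive-class probability in [0, 1] for each descriptor row."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features:
            raise InvalidModelError(
                f"descriptor length {X.shape[1]} does not match trained "
                f"model ({self.n_features})"
            )
        return self.model.predict_proba(X)[:, 1]

    def predict(self, X: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.scores(X) >= threshold).astype(int)

    def save(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "model": self.model,
            "feature_config": self.feature_config.to_dict(),
            "metadata": self.metadata,
        }
        joblib.dump(payload, path)
        return path

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        payload = joblib.load(path)
        if not isinstance(payload, dict) or payload.get("format") != MODEL_FORMAT:
            raise InvalidModelError(f"{path} is not a wildcount model file")
        return cls(
            model=payload["model"],
            feature_config=FeatureConfig.from_dict(payload["feature_config"]),
            metadata=payload.get("metadata", {}),
        )


# ---------------------------------------------------------------------------
# contrast pre-filter


def local_contrast_mask(
    image: np.ndarray, window: int = 5, threshold: float = 0.08
) -> np.ndarray:
    """True where the windowed intensity standard deviation exceeds threshold.

    Uniform regions (flat background) come out False and are skipped by the
    detector.  ``window`` must be odd and >= 3; borders use reflection.
    """
    if window < 3 or window % 2 == 0:
        raise InvalidParameterError("window must be odd and >= 3")
    image = np.asarray(to_grayscale(image), dtype=float)
    mean = ndimage.uniform_filter(image, window, mode="reflect")
    mean_sq = ndimage.uniform_filter(image * image, window, mode="reflect")
    var = np.maximum(mean_sq - mean * mean, 0.0)
    return np.sqrt(var) > threshold


# ---------------------------------------------------------------------------
# training


def train(
    samples: TrainingSet,
    feature_config: FeatureConfig | None = None,
    config: DetectorConfig | None = None,
) -> PixelClassifier:
    """Fit the boosted tree ensemble on labelled descriptors.

    Requires at least two samples of each class.  The returned classifier
    carries the feature configuration and training metadata so that
    detection can verify descriptor compatibility.
    """
    config = config or DetectorConfig()
    feature_config = feature_config or FeatureConfig()
    classes, counts = np.unique(samples.y, return_counts=True)
    if len(classes) < 2:
        raise InvalidInputError("training set must contain both classes")
    if counts.min() < 2:
        raise InvalidInputError("need at least 2 samples per class")
    base = DecisionTreeClassifier(max_depth=config.max_depth, random_state=config.seed)
    model = AdaBoostClassifier(
        estimator=base,
        n_estimators=config.n_estimators,
        learning_rate=config.learning_rate,
        random_state=config.seed,
    )
    model.fit(samples.X, samples.y)
    acc = float(model.score(samples.X, samples.y))
    logger.info("trained on %d samples, training accuracy %.3f", len(samples), acc)
    return PixelClassifier(
        model=model,
        feature_config=feature_config,
        metadata={
            "n_positive": int((samples.y == 1).sum()),
            "n_negative": int((samples.y == 0).sum()),
            "seed": config.seed,
            "training_accuracy": acc,
            "detector_config": config.to_dict(),
        },
    )


def harvest_training_set(
    images: Sequence[np.ndarray],
    truths: Sequence[np.ndarray],
    extractor: FourierHOG,
    n_negative_per_image: int = 20,
    rng: np.random.Generator | None = None,
    image_ids: Sequence[str] | None = None,
    positive_jitter: int = 2,
) -> TrainingSet:
    """Build descriptors from annotated images.

    One positive is taken per annotated centroid, displaced by a uniform
    integer offset of up to ``positive_jitter`` pixels per axis: manual
    centroid clicks are not pixel-accurate, and the per-pixel detector
    must respond positively over a small contiguous neighbourhood of the
    object centre for grouping to yield one component per animal.
    Negatives are sampled uniformly at random, at least one
    window-diameter away from every centroid (and half a window from the
    border).
    """
    rng = rng or np.random.default_rng(0)
    radius = extractor.config.radius
    exclusion = 2.0 * extractor.config.window  # one window-diameter clearance
    rows: list[np.ndarray] = []
    labels: list[int] = []
    source: list[str] = []
    for i, (image, truth) in enumerate(zip(images, truths)):
        image_id = image_ids[i] if image_ids is not None else f"image{i}"
        gray = to_grayscale(image)
        maps = extractor.feature_maps(gray)
        h, w = gray.shape
        centroids = np.asarray(truth, dtype=float).reshape(-1, 2)
        for (x, y) in centroids:
            px = int(round(x)) + int(rng.integers(-positive_jitter, positive_jitter + 1))
            py = int(round(y)) + int(rng.integers(-positive_jitter, positive_jitter + 1))
            px = min(max(px, 0), w - 1)
            py = min(max(py, 0), h - 1)
            rows.append(maps[py, px])
            labels.append(1)
            source.append(f"{image_id}:+({x:.0f},{y:.0f})")
        h, w = gray.shape
        n_found = 0
        attempts = 0
        while n_found < n_negative_per_image and attempts < 200 * n_negative_per_image:
            attempts += 1
            x = rng.integers(radius, w - radius)
            y = rng.integers(radius, h - radius)
            if centroids.size and np.min(
                (centroids[:, 0] - x) ** 2 + (centroids[:, 1] - y) ** 2
            ) < (exclusion / 2.0) ** 2:
                continue
            rows.append(maps[y, x])
            labels.append(0)
            source.append(f"{image_id}:-({x},{y})")
            n_found += 1
    return TrainingSet(X=np.asarray(rows), y=np.asarray(labels), source=source)


CorrectionCallback = Callable[[int, "DetectionResult"], Sequence[bool]]


def bootstrap_train(
    initial: TrainingSet,
    images: Sequence[np.ndarray],
    callback: CorrectionCallback,
    extractor: FourierHOG,
    feature_config: FeatureConfig | None = None,
    config: DetectorConfig | None = None,
    checkpoint_path: str | Path | None = None,
) -> TrainingSet:
    """One check-and-correct enlargement round of the training set.

    A classifier trained on ``initial`` is run over the (unlabelled)
    ``images``; for each image the ``callback(image_index, result)`` returns
    one boolean per detection — True confirms it as an animal, False marks
    it a false positive — and the corresponding descriptors are appended
    with the corrected labels.  If the callback raises, the set grown so
    far is preserved at ``checkpoint_path`` (when given) before the error
    propagates.
    """
    config = config or DetectorConfig()
    feature_config = feature_config or extractor.config
    classifier = train(initial, feature_config=feature_config, config=config)
    grown = initial
    for i, image in enumerate(images):
        gray = to_grayscale(image)
        maps = extractor.feature_maps(gray)
        result = detect(gray, classifier, config, extractor=extractor)
        if not result.components:
            continue
        try:
            verdicts = list(callback(i, result))
        except Exception:
            if checkpoint_path is not None:
                joblib.dump(grown, Path(checkpoint_path))
                logger.error(
                    "correction callback failed on image %d; partial set "
                    "(%d samples) saved to %s", i, len(grown), checkpoint_path,
                )
            raise
        if len(verdicts) != len(result.components):
            raise InvalidInputError(
                "callback must return one verdict per detection"
            )
        X = np.asarray(
            [maps[int(round(d.y)), int(round(d.x))] for d in result.components]
        )
        y = np.asarray([1 if v else 0 for v in verdicts], dtype=int)
        src = [f"bootstrap:image{i}:({d.x:.0f},{d.y:.0f})" for d in result.components]
        grown = grown.extend(X, y, src)
        logger.info(
            "bootstrap image %d: %d detections (%d confirmed), set size %d",
            i, len(verdicts), int(y.sum()), len(grown),
        )
    return grown


# ---------------------------------------------------------------------------
# detection


def detect(
    image: np.ndarray,
    classifier: PixelClassifier,
    config: DetectorConfig | None = None,
    extractor: FourierHOG | None = None,
) -> DetectionResult:
    """Full scan -> classify -> group pipeline on one image.

    Only pixels inside the local-contrast mask are classified; everything
    else is negative by construction.  Positive pixels are grouped with
    8-connectivity and each component becomes one counted detection
    (centroid, area, max pixel score).
    """
    config = config or DetectorConfig()
    if extractor is None:
        extractor = FourierHOG(classifier.feature_config)
    elif extractor.config != classifier.feature_config:
        raise InvalidModelError(
            "extractor feature configuration does not match the trained model"
        )
    if len(extractor.spec) != classifier.n_features:
        raise InvalidModelError(
            "descriptor spec length does not match the trained model"
        )
    gray = to_grayscale(image)
    mask = local_contrast_mask(gray, config.contrast_window, config.contrast_threshold)
    if config.stride > 1:
        grid = np.zeros_like(mask)
        grid[:: config.stride, :: config.stride] = True
        mask = mask & grid
    pos_mask = np.zeros_like(mask)
    scores_map = np.zeros(gray.shape, dtype=float)
    if mask.any():
        maps = extractor.feature_maps(gray)
        ys, xs = np.nonzero(mask)
        scores = classifier.scores(maps[ys, xs])
        positive = scores >= config.score_threshold
        pos_mask[ys[positive], xs[positive]] = True
        scores_map[ys, xs] = scores
    labels, n = ndimage.label(pos_mask, structure=np.ones((3, 3), dtype=int))
    components: list[Detection] = []
    if n:
        areas = ndimage.sum_labels(pos_mask, labels, index=np.arange(1, n + 1))
        centroids = ndimage.center_of_mass(pos_mask, labels, np.arange(1, n + 1))
        peak = ndimage.maximum(scores_map, labels, index=np.arange(1, n + 1))
        for (cy, cx), area, s in zip(centroids, areas, peak):
            if area < config.min_area:
                continue
            components.append(
                Detection(x=float(cx), y=float(cy), area=int(area), score=float(s))
            )
    return DetectionResult(mask=pos_mask, components=components, count=len(components))
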