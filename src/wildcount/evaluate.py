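"""Count-comparison statistics for aerial census images.

Implements the metrics used to compare automated and manual per-image
counts: totals, per-image means, coefficient of variation, RMS and mean
signed error (``D_i`` = count difference on image ``i``), detection
precision/recall from centroid matching, and the light-level regression
that relates under-counting to image brightness.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import (
    InsufficientDataError,
    InvalidInputError,
    UndefinedStatisticError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "CountTable",
    "ConfusionCounts",
    "rms_error",
    "mean_error",
    "summary_stats",
    "match_detections",
    "precision_recall",
    "undercount_regression",
    "compute_light_level",
    "metrics_report",
]

#: Counter columns a full count table carries, in report order.
COUNTER_COLUMNS = ("first_manual", "second_manual", "final_manual", "automated")


@dataclass
class CountTable:
    """Per-image aligned counts (one row per image).

    Wraps a DataFrame keyed by ``image_id`` with integer count columns;
    ``final_manual`` is the reference ("true") count and must be complete.
    Additional ``automated_<n>`` columns (counts at different training-set
    sizes) are carried through untouched.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        if "image_id" not in self.frame.columns:
            raise InvalidInputError("count table requires an image_id column")
        if "final_manual" in self.frame.columns and (
            self.frame["final_manual"].isna().any()
        ):
            raise InvalidInputError("final_manual column has missing values")

    @property
    def n(self) -> int:
        return len(self.frame)

    def column(self, name: str) -> np.ndarray:
        if name not in self.frame.columns:
            raise InvalidInputError(f"count table has no column {name!r}")
        return self.frame[name].to_numpy(dtype=float)


@dataclass(frozen=True)
class ConfusionCounts:
    """Detection confusion totals; TN counts animal-sized background regions."""

    tp: int
    fp: int
    fn: int
    tn: int | None = None

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "fn"):
            if getattr(self, name) < 0:
                raise InvalidInputError(f"{name} must be non-negative")


def _paired(counts, truth) -> tuple[np.ndarray, np.ndarray]:
    counts = np.asarray(counts, dtype=float)
    truth = np.asarray(truth, dtype=float)
    if counts.shape != truth.shape or counts.ndim != 1 or counts.size == 0:
        raise InvalidInputError("counts and truth must be equal-length 1-d, n >= 1")
    return counts, truth


def rms_error(counts, truth) -> float:
    """Root mean square of per-image count differences, sqrt(1/N sum D_i^2)."""
    counts, truth = _paired(counts, truth)
    d = counts - truth
    return float(np.sqrt(np.mean(d * d)))


def mean_error(counts, truth) -> float:
    """Mean signed per-image count difference, 1/N sum D_i."""
    counts, truth = _paired(counts, truth)
    return float(np.mean(counts - truth))


def summary_stats(values) -> tuple[float, float, float]:
    """(total, mean per image, coefficient of variation) of a count column.

    CV uses the sample standard deviation (N-1 denominator) divided by the
    mean; undefined when the mean is zero.
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or values.size < 2:
        raise InvalidInputError("need a 1-d column with N >= 2")
    total = float(values.sum())
    mean = total / values.size
    if mean == 0:
        raise UndefinedStatisticError("coefficient of variation undefined: mean is 0")
    cv = float(np.std(values, ddof=1) / mean)
    return total, mean, cv


def match_detections(
    detections,
    truth,
    radius: float,
    image_shape: tuple[int, int] | None = None,
    window: int | None = None,
) -> ConfusionCounts:
    """Greedy nearest-first matching of detections to true centroids.

    Pairs are formed in order of increasing distance, each detection and
    each truth used at most once, only within ``radius`` pixels.  TP =
    matched pairs, FP = unmatched detections, FN = unmatched truths.  When
    ``image_shape`` and ``window`` are given, TN is estimated as the number
    of non-overlapping animal-sized (window x window) regions in the image
    not accounted for by TP/FP/FN.
    """
    if radius <= 0:
        raise InvalidInputError("radius must be positive")
    det = np.asarray(detections, dtype=float).reshape(-1, 2)
    tru = np.asarray(truth, dtype=float).reshape(-1, 2)
    pairs = []
    for i in range(det.shape[0]):
        d = np.hypot(det[i, 0] - tru[:, 0], det[i, 1] - tru[:, 1])
        for j in np.nonzero(d <= radius)[0]:
            pairs.append((d[j], i, int(j)))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    fp = det.shape[0] - tp
    fn = tru.shape[0] - tp
    tn = None
    if image_shape is not None and window is not None:
        regions = int(image_shape[0] * image_shape[1] // (window * window))
        tn = max(regions - tp - fp - fn, 0)
    return ConfusionCounts(tp=tp, fp=fp, fn=fn, tn=tn)


def precision_recall(c: ConfusionCounts) -> tuple[float, float]:
    """precision = TP/(TP+FP), recall = TP/(TP+FN); TN is not used."""
    if c.tp + c.fp == 0 or c.tp + c.fn == 0:
        raise UndefinedStatisticError("precision/recall undefined: zero denominator")
    return c.tp / (c.tp + c.fp), c.tp / (c.tp + c.fn)


def undercount_regression(
    automated,
    truth,
    light_levels,
) -> tuple[float, float, int]:
    """OLS of the under-count fraction on image light level.

    The under-count fraction for image i is ``1 - automated_i / true_i``.
    Images where the algorithm over-counts (automated > true) are excluded,
    as are images with a zero true count (fraction undefined); exclusions
    are logged.  Returns ``(slope, r_squared, n_used)`` and raises when
    fewer than 3 images remain.
    """
    a = np.asarray(automated, dtype=float)
    t = np.asarray(truth, dtype=float)
    ll = np.asarray(light_levels, dtype=float)
    if not (a.shape == t.shape == ll.shape) or a.ndim != 1:
        raise InvalidInputError("automated, truth and light_levels must align")
    keep = (t > 0) & (a <= t)
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info(
            "undercount_regression: excluded %d images (over-counted or "
            "zero true count)", n_drop,
        )
    if keep.sum() < 3:
        raise InsufficientDataError(
            f"only {int(keep.sum())} images retained; need >= 3"
        )
    frac = 1.0 - a[keep] / t[keep]
    if np.ptp(frac) == 0:  # constant response: flat fit explains nothing
        return 0.0, 0.0, int(keep.sum())
    res = stats.linregress(ll[keep], frac)
    return float(res.slope), float(res.rvalue**2), int(keep.sum())


def compute_light_level(image: np.ndarray) -> float:
    """Mean of the HSV value channel (per-pixel max of R, G, B in [0, 1])."""
    image = np.asarray(image, dtype=float)
    if image.size == 0:
        raise InvalidInputError("empty image")
    if image.ndim == 2:
        value = image
    elif image.ndim == 3 and image.shape[2] in (3, 4):
        value = image[..., :3].max(axis=2)
    else:
        raise InvalidInputError(f"cannot interpret image of shape {image.shape}")
    return float(value.mean())


def metrics_report(table: CountTable, reference: str = "final_manual") -> dict:
    """Summary statistics for every counter column present in the table.

    For each counter: total, mean per image, CV, and (except for the
    reference itself) RMS and mean signed error against the reference.
    ``automated_<n>`` columns are included alongside the four standard ones.
    """
    ref = table.column(reference)
    report: dict = {"n_images": table.n, "reference": reference, "counters": {}}
    columns = [c for c in COUNTER_COLUMNS if c in table.frame.columns]
    columns += sorted(
        c for c in table.frame.columns
        if c.startswith("automated_") and c not in columns
    )
    for col in columns:
        values = table.column(col)
        total, mean, cv = summary_stats(values)
        entry = {
            "total": total,
            "mean_per_image": mean,
            "coefficient_of_variation": cv,
        }
        if col != reference:
            entry["rms_error"] = rms_error(values, ref)
            entry["mean_error"] = mean_error(values, ref)
        report["counters"][col] = entry
    return report
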