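"""Excess-green plant/soil segmentation and its quality metrics.

The excess green index on chromaticity-normalized channels,

    ExG = 2g - r - b,   (r, g, b) = (R, G, B) / (R + G + B),

is high for green vegetation and near zero for soil, so a single
threshold on the ExG histogram separates plant from background.  A
manual-reference labelling (per-channel mean +/- 1 sd band over sampled
plant pixels) provides the ground-truth mask against which precision,
sensitivity, F-score and accuracy are scored.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from skimage.filters import threshold_otsu

__all__ = [
    "ConfusionCounts",
    "SegmentationMetrics",
    "excess_green",
    "segment_exg",
    "reference_labeling",
    "confusion",
    "metrics",
]


def excess_green(rgb) -> np.ndarray:
    """ExG = 2g - r - b per pixel on chromaticity-normalized channels.

    Pure green maps to 2, achromatic pixels (including pure black, where
    R+G+B = 0) to exactly 0; the range is [-1, 2].  Invariant under
    uniform channel scaling up to 8-bit quantization.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an H x W x 3 raster, got shape {arr.shape}")
    s = arr.sum(axis=2)
    with np.errstate(invalid="ignore", divide="ignore"):
        chroma = arr / s[..., None]
    exg = 2 * chroma[..., 1] - chroma[..., 0] - chroma[..., 2]
    exg[s == 0] = 0.0
    return exg


def segment_exg(exg, method: str = "otsu", threshold: float | None = None) -> np.ndarray:
    """Binarize an ExG map: pixel = 1 iff ExG > threshold.

    ``method='otsu'`` picks the threshold maximizing between-class
    variance of the 256-bin ExG histogram; ``method='fixed'`` uses the
    supplied scalar.  A constant map under Otsu yields an all-zero mask
    with a warning (there is only one class to find).
    """
    arr = np.asarray(exg, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ExG map must be finite")
    if method == "fixed":
        if threshold is None:
            raise ValueError("method='fixed' requires a threshold")
        thr = float(threshold)
    elif method == "otsu":
        if np.ptp(arr) == 0.0:
            warnings.warn(
                "constant ExG map: only one class present, returning all-zero mask",
                stacklevel=2,
            )
            return np.zeros(arr.shape, dtype=np.uint8)
        thr = float(threshold_otsu(arr, nbins=256))
    else:
        raise ValueError(f"unknown method {method!r}; use 'otsu' or 'fixed'")
    return (arr > thr).astype(np.uint8)


def reference_labeling(rgb, samples) -> np.ndarray:
    """Manual-reference binarization from sampled plant pixels.

    ``samples`` are (row, col) coordinates of pixels chosen as
    representative plant colors (ten in the original protocol).  Per
    channel, the mean and standard deviation over the samples define a
    band [mean - sd, mean + sd]; a pixel is labelled plant (1) iff every
    channel lies inside its band.
    """
    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an H x W x 3 raster")
    coords = np.asarray(samples, dtype=int)
    if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] < 2:
        raise ValueError("need at least 2 (row, col) sample coordinates")
    h, w = arr.shape[:2]
    if (
        (coords[:, 0] < 0).any()
        or (coords[:, 0] >= h).any()
        or (coords[:, 1] < 0).any()
        or (coords[:, 1] >= w).any()
    ):
        raise IndexError("sample coordinate outside the image")
    picked = arr[coords[:, 0], coords[:, 1]]  # (n, 3)
    mean = picked.mean(axis=0)
    sd = picked.std(axis=0)
    inside = (arr >= mean - sd) & (arr <= mean + sd)
    return inside.all(axis=2).astype(np.uint8)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion(pred, ref) -> ConfusionCounts:
    """Pixel confusion counts of a predicted mask against a reference."""
    p = np.asarray(pred).astype(bool)
    r = np.asarray(ref).astype(bool)
    if p.shape != r.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {r.shape}")
    return ConfusionCounts(
        tp=int(np.sum(p & r)),
        fp=int(np.sum(p & ~r)),
        fn=int(np.sum(~p & r)),
        tn=int(np.sum(~p & ~r)),
    )


@dataclass(frozen=True)
class SegmentationMetrics:
    """Precision, sensitivity, F-score, accuracy, total error - all in [0, 1].

    Edge conventions: precision and sensitivity are 0 when their
    denominator is 0; the F-score is 0 whenever TP = 0 (so the score
    runs from 0 at no true positives to 1 at perfect classification).
    ``processing_time`` is informational only.
    """

    precision: float
    sensitivity: float
    f_score: float
    accuracy: float
    total_error: float
    processing_time: float = 0.0

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "sensitivity": self.sensitivity,
            "f_score": self.f_score,
            "accuracy": self.accuracy,
            "total_error": self.total_error,
            "processing_time": self.processing_time,
        }


def metrics(c: ConfusionCounts, processing_time: float = 0.0) -> SegmentationMetrics:
    """Classification metrics from confusion counts."""
    if c.total == 0:
        raise ValueError("empty confusion counts")
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else 0.0
    sensitivity = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    f_score = (
        2 * precision * sensitivity / (precision + sensitivity)
        if c.tp > 0
        else 0.0
    )
    accuracy = (c.tp + c.tn) / c.total
    return SegmentationMetrics(
        precision=precision,
        sensitivity=sensitivity,
        f_score=f_score,
        accuracy=accuracy,
        total_error=1.0 - accuracy,
        processing_time=processing_time,
    )
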