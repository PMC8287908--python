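"""Laplacian-of-Gaussian baseline detector with quantile threshold selection.

Mirrors the classical workflow: a scale-normalized LoG response at a
blob diameter, local maxima as candidate spots with the response value
as a quality score, and a data-driven threshold chosen by grid search —
per-image qualities are normalized to that image's median, twenty
linearly distributed quantiles of the pooled normalized qualities are
tried as cutoffs, and the (diameter, quantile value) pair maximizing the
mean F1 integral is selected.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

from .metrics import f1_integral

__all__ = ["log_detect", "select_threshold", "LoGDetector"]

# blob radius r = sigma * sqrt(2) for a scale-matched LoG, so
# sigma = diameter / (2 * sqrt(2))
_DIAMETER_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0))

# quantile levels: linspace(0, 0.95, 20); including 1.0 would discard
# every detection
_QUANTILE_LEVELS = np.linspace(0.0, 0.95, 20)


def log_detect(image: np.ndarray, diameter: float):
    """Detect blobs of a given diameter with a LoG filter.

    Returns ``(coords, qualities)``: sub-pixel (row, col) positions of the
    strictly positive local maxima of the scale-normalized negated LoG
    response, refined per axis by quadratic interpolation of the peak,
    and the peak response values as quality scores.
    """
    if diameter <= 0:
        raise ValueError("diameter must be > 0")
    image = np.asarray(image, dtype=np.float64)
    sigma = diameter * _DIAMETER_TO_SIGMA
    # bright blobs give negative LoG; negate and scale-normalize by sigma^2
    # (truncate=8 keeps the discrete kernel near zero-sum so constant
    # backgrounds produce a response at numerical-noise level only)
    resp = -(sigma**2) * ndimage.gaussian_laplace(image, sigma, truncate=8.0)
    # strict maximum over the 8-neighborhood, above a numerical floor:
    # blank images and flat backgrounds produce no detections
    neighbors = np.ones((3, 3), dtype=bool)
    neighbors[1, 1] = False
    is_max = resp > ndimage.maximum_filter(resp, footprint=neighbors)
    is_max &= resp > 1e-9 * max(float(np.abs(image).max()), 1.0)
    rows, cols = np.nonzero(is_max)
    coords, quals = [], []
    h, w = resp.shape
    for r, c in zip(rows, cols):
        dr = dc = 0.0
        if 0 < r < h - 1:
            denom = resp[r - 1, c] - 2 * resp[r, c] + resp[r + 1, c]
            if denom != 0:
                dr = 0.5 * (resp[r - 1, c] - resp[r + 1, c]) / denom
        if 0 < c < w - 1:
            denom = resp[r, c - 1] - 2 * resp[r, c] + resp[r, c + 1]
            if denom != 0:
                dc = 0.5 * (resp[r, c - 1] - resp[r, c + 1]) / denom
        coords.append((r + np.clip(dr, -0.5, 0.5), c + np.clip(dc, -0.5, 0.5)))
        quals.append(resp[r, c])
    if not coords:
        return np.empty((0, 2)), np.empty(0)
    return np.asarray(coords, dtype=np.float64), np.asarray(quals)


def _normalized_qualities(qualities: np.ndarray) -> np.ndarray:
    """Divide an image's quality scores by their median (guarding 0)."""
    if len(qualities) == 0:
        return qualities
    med = np.median(qualities)
    return qualities / med if med > 0 else qualities.astype(np.float64)


@dataclass
class ThresholdSearchResult:
    diameter: float
    threshold: float
    mean_f1_integral: float


def select_threshold(images, truths, diameters):
    """Grid-search blob diameter and quality quantile threshold.

    For each diameter, every image is detected, its qualities are
    normalized to the image's median, and the 20 quantile levels of the
    pooled normalized qualities are tried as absolute cutoffs; the
    (diameter, quantile value) pair maximizing the mean F1 integral over
    the images is returned, together with the full search table.
    """
    if len(images) != len(truths):
        raise ValueError("images and truths must have equal length")
    if sum(len(np.asarray(t).reshape(-1, 2)) for t in truths) == 0:
        raise ValueError("threshold selection needs at least one ground-truth "
                         "spot")
    diameters = list(diameters)
    if not diameters:
        raise ValueError("no diameters to search")
    best = None
    table = []
    for diameter in diameters:
        detections = [log_detect(img, diameter) for img in images]
        norm_quals = [_normalized_qualities(q) for _, q in detections]
        pooled = np.concatenate([q for q in norm_quals if len(q)]) \
            if any(len(q) for q in norm_quals) else np.empty(0)
        if len(pooled) == 0:
            continue
        for level in _QUANTILE_LEVELS:
            cutoff = float(np.quantile(pooled, level))
            f1s = [
                f1_integral(coords[quals >= cutoff], truth)
                for (coords, _), quals, truth in zip(detections, norm_quals,
                                                     truths)
            ]
            mean_f1 = float(np.mean(f1s))
            table.append(ThresholdSearchResult(diameter, cutoff, mean_f1))
            if best is None or mean_f1 > best.mean_f1_integral:
                best = ThresholdSearchResult(diameter, cutoff, mean_f1)
    if best is None:
        raise RuntimeError("no detections at any searched diameter")
    return best, table


class LoGDetector(BaseEstimator):
    """Threshold-selected LoG spot detector (scikit-learn interface).

    ``fit(X, y)`` runs the diameter/quantile grid search on labeled
    images; ``predict(X)`` detects at the selected diameter and keeps
    detections whose median-normalized quality reaches the selected
    threshold.
    """

    def __init__(self, diameters=(3.0, 5.0, 7.0)):
        self.diameters = diameters

    def fit(self, X, y):
        best, table = select_threshold(X, y, self.diameters)
        self.diameter_ = best.diameter
        self.threshold_ = best.threshold
        self.best_score_ = best.mean_f1_integral
        self.search_results_ = table
        return self

    def predict(self, X) -> list[np.ndarray]:
        if not hasattr(self, "diameter_"):
            raise RuntimeError("LoGDetector is not fitted")
        out = []
        for img in X:
            coords, quals = log_detect(img, self.diameter_)
            out.append(coords[_normalized_qualities(quals) >= self.threshold_])
        return out

    def score(self, X, y) -> float:
        return float(np.mean([
            f1_integral(p, t) for p, t in zip(self.predict(X), y)
        ]))
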