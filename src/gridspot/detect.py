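"""Inference: sub-pixel spot prediction on new images, CSV export, and
optional Gaussian refinement of predicted centers."""

from __future__ import annotations

import csv

import numpy as np
from scipy.optimize import least_squares

from .grid import decode_grid
from .network import GridNet

__all__ = [
    "standardize_image",
    "pad_to_divisor",
    "predict_image",
    "refine_gaussian",
    "write_coords_csv",
]


def standardize_image(image: np.ndarray, eps: float = 1e-8) -> np.ndarray:
    """Per-image standardization: zero mean, unit sd (plus eps guard).

    Applied identically at training and prediction time, which makes the
    detector robust to the absolute brightness and background offsets
    that vary between microscopy acquisitions.
    """
    image = np.asarray(image, dtype=np.float32)
    return (image - image.mean()) / (image.std() + eps)


def pad_to_divisor(image: np.ndarray, divisor: int) -> np.ndarray:
    """Reflect-pad bottom/right so both sides are multiples of ``divisor``."""
    h, w = image.shape
    ph = (-h) % divisor
    pw = (-w) % divisor
    if ph == 0 and pw == 0:
        return image
    return np.pad(image, ((0, ph), (0, pw)), mode="reflect")


def predict_image(model: GridNet, image: np.ndarray,
                  prob_threshold: float = 0.5,
                  refine: bool = False) -> np.ndarray:
    """Predict sub-pixel (row, col) spot coordinates for one image.

    The image is standardized, reflect-padded to the divisibility the
    network requires, run through the network, and decoded at
    ``prob_threshold``; coordinates falling in the padded margins are
    discarded so every returned coordinate lies in the original frame.
    """
    image = np.asarray(image, dtype=np.float64)
    if image.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {image.shape}")
    h, w = image.shape
    x = pad_to_divisor(standardize_image(image), model.config.divisor)
    grid = model(x[None])[0]
    coords = decode_grid(grid, cell_size=model.config.cell_size,
                         prob_threshold=prob_threshold)
    if len(coords):
        keep = (coords[:, 0] < h) & (coords[:, 1] < w)
        coords = coords[keep]
    if refine and len(coords):
        coords = refine_gaussian(image, coords)
    return coords


def _gaussian2d(params, rr, cc):
    amp, r0, c0, sigma, offset = params
    return amp * np.exp(-((rr - r0) ** 2 + (cc - c0) ** 2)
                        / (2.0 * sigma**2)) + offset


def refine_gaussian(image: np.ndarray, coords, window: int = 7) -> np.ndarray:
    """Refine each coordinate by a least-squares 2D Gaussian fit.

    An isotropic Gaussian (amplitude, center, sigma, offset) is fitted on
    a ``window`` x ``window`` patch around the rounded coordinate (clipped
    at image borders), initialized at the input coordinate.  If the fit
    fails or moves the center by more than window/2, the original
    coordinate is kept.
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    image = np.asarray(image, dtype=np.float64)
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    h, w = image.shape
    half = window // 2
    out = coords.copy()
    for k, (r, c) in enumerate(coords):
        ri, ci = int(round(r)), int(round(c))
        r_lo, r_hi = max(0, ri - half), min(h, ri + half + 1)
        c_lo, c_hi = max(0, ci - half), min(w, ci + half + 1)
        patch = image[r_lo:r_hi, c_lo:c_hi]
        if patch.size < 6 or np.ptp(patch) == 0:
            continue  # flat or degenerate window: keep the input coordinate
        rr, cc = np.meshgrid(np.arange(r_lo, r_hi), np.arange(c_lo, c_hi),
                             indexing="ij")
        r0 = min(max(r, r_lo), r_hi - 1)
        c0 = min(max(c, c_lo), c_hi - 1)
        p0 = [max(np.ptp(patch), 1e-6), r0, c0, 1.5, patch.min()]
        try:
            fit = least_squares(
                lambda p: (_gaussian2d(p, rr, cc) - patch).ravel(), p0,
                bounds=([0, r_lo - 1, c_lo - 1, 0.3, -np.inf],
                        [np.inf, r_hi, c_hi, window, np.inf]),
                max_nfev=200,
            )
        except ValueError:
            continue
        if not fit.success:
            continue
        r_fit, c_fit = fit.x[1], fit.x[2]
        if np.hypot(r_fit - r, c_fit - c) > window / 2:
            continue
        out[k] = (r_fit, c_fit)
    return out


def write_coords_csv(coords, path) -> None:
    """Write coordinates as a CSV with header ``x,y``.

    x is the column coordinate and y the row coordinate (the plotting
    convention); values keep full float precision.
    """
    coords = np.asarray(coords, dtype=np.float64).reshape(-1, 2)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["x", "y"])
        for r, c in coords:
            writer.writerow([repr(float(c)), repr(float(r))])
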