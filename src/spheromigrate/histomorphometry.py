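"""Threshold-based positive-pixel histomorphometry.

Scores a grayscale immunofluorescence section by the fraction of pixels
whose intensity lies strictly above a threshold (chosen by the analyst to
exclude unspecific staining), and normalizes per-sample values to the mean
of a control group so treatment effects read as fold changes.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from skimage.filters import threshold_otsu

from .exceptions import EmptyMaskError, UnsupportedImageError
from .io import ImageStack

__all__ = [
    "PositivePixelResult",
    "positive_pixel_fraction",
    "suggest_threshold",
    "normalize_to_control",
]


@dataclass
class PositivePixelResult:
    """Positive-pixel score of one section."""

    n_total: int
    n_positive: int
    fraction: float
    threshold: float


def _as_2d(image) -> np.ndarray:
    if isinstance(image, ImageStack):
        if image.data.shape[0] != 1:
            raise UnsupportedImageError(
                "positive-pixel scoring expects a 2D section, got a z-stack"
            )
        return image.data[0]
    arr = np.asarray(image)
    if arr.ndim == 3 and arr.shape[0] == 1:
        arr = arr[0]
    if arr.ndim != 2:
        raise UnsupportedImageError(f"expected a 2D image, got {arr.ndim} dimensions")
    return arr


def positive_pixel_fraction(image, threshold: float, roi=None) -> PositivePixelResult:
    """Fraction of pixels strictly above ``threshold`` within ``roi``.

    Parameters
    ----------
    image : ImageStack (single plane) or 2D ndarray
    threshold : float
        Intensity cut-off; pixels count as positive iff intensity > threshold.
    roi : 2D boolean ndarray, optional
        Region of interest; defaults to the whole image.
    """
    arr = _as_2d(image)
    if roi is not None:
        roi = np.asarray(roi, dtype=bool)
        if roi.shape != arr.shape:
            raise ValueError(f"roi shape {roi.shape} does not match image {arr.shape}")
        if not roi.any():
            raise EmptyMaskError("empty roi")
        values = arr[roi]
    else:
        values = arr.ravel()
    n_total = int(values.size)
    n_positive = int(np.count_nonzero(values > threshold))
    return PositivePixelResult(
        n_total=n_total,
        n_positive=n_positive,
        fraction=n_positive / n_total,
        threshold=float(threshold),
    )


def suggest_threshold(image, roi=None) -> float:
    """Otsu threshold suggestion for a section (advisory; never auto-applied)."""
    arr = _as_2d(image)
    values = arr[np.asarray(roi, dtype=bool)] if roi is not None else arr
    return float(threshold_otsu(values))


def normalize_to_control(values, control):
    """Divide per-sample values by the mean of a control group.

    Parameters
    ----------
    values : pandas Series, mapping or array-like
        One value per sample (e.g. positive-pixel fractions).
    control : sequence of labels or boolean mask
        Which samples constitute the control group; with a labeled Series
        or mapping, a list of sample names, otherwise a boolean mask or
        index positions.

    Returns
    -------
    Same shape as ``values``: each value divided by the control mean, so
    the control group's normalized mean equals 1 exactly.
    """
    series = pd.Series(values, dtype=float)
    control = list(control) if not isinstance(control, np.ndarray) else control
    if len(control) == 0:
        raise ValueError("control group must be non-empty")
    if isinstance(control, np.ndarray) and control.dtype == bool:
        ctrl_values = series[control]
    elif all(isinstance(c, (bool, np.bool_)) for c in control):
        ctrl_values = series[np.asarray(control, dtype=bool)]
    else:
        ctrl_values = series.loc[control]
    if len(ctrl_values) == 0:
        raise ValueError("control group selects no samples")
    mean = float(ctrl_values.mean())
    if mean <= 0:
        raise ValueError(f"control mean must be positive, got {mean}")
    normalized = series / mean
    if isinstance(values, pd.Series):
        return normalized
    if isinstance(values, dict):
        return normalized.to_dict()
    return normalized.to_numpy()
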