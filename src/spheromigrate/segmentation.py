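"""Foreground segmentation and spheroid-core localisation.

The f-actin channel is bright wherever cells are, so the foreground mask is
obtained by global thresholding (Otsu by default, or a fixed value for
controlled experiments).  The spheroid center is the deepest interior point
of the largest foreground blob — the argmax of the Euclidean distance
transform — which is robust to asymmetric sprouts that would bias a
centroid.  The core region is the foreground inside the maximal inscribed
ball around that center.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .exceptions import DegenerateImageError, EmptyMaskError, NoForegroundError
from .io import ImageStack

__all__ = [
    "ForegroundMask",
    "CoreEstimate",
    "segment_foreground",
    "estimate_core",
    "locate_core",
    "inscribed_core_mask",
]

logger = logging.getLogger(__name__)


@dataclass
class ForegroundMask:
    """Boolean stained-pixel mask with the threshold that produced it."""

    mask: np.ndarray
    threshold_used: float
    method: str
    smooth_sigma: float = 0.0


@dataclass
class CoreEstimate:
    """Spheroid center and core region.

    ``center`` is the voxel of maximal Euclidean distance-transform value
    within the largest connected foreground component (ties broken by the
    lowest lexicographic index); ``core_radius_est`` is that maximal EDT
    value in physical units, i.e. the radius of the largest ball inscribed
    in the spheroid body; ``core_mask`` is the connected foreground region
    strictly inside that ball around the center.
    """

    center: tuple[int, ...]
    core_radius_est: float
    core_mask: np.ndarray


def _as_bool_mask(mask) -> np.ndarray:
    if isinstance(mask, ForegroundMask):
        mask = mask.mask
    return np.asarray(mask, dtype=bool)


def _distance_grid(shape, center, spacing) -> np.ndarray:
    """Physical Euclidean distance of every voxel from ``center``."""
    spacing = np.ones(len(shape)) if spacing is None else np.asarray(spacing, dtype=float)
    axes = [
        ((np.arange(n) - c) * s) ** 2
        for n, c, s in zip(shape, center, spacing)
    ]
    grid = axes[0]
    for a in axes[1:]:
        grid = grid[..., np.newaxis] + a
    return np.sqrt(grid)


def segment_foreground(
    stack,
    method: str = "otsu",
    fixed_threshold: float | None = None,
    smooth_sigma: float = 0.0,
) -> ForegroundMask:
    """Threshold an intensity image into a stained-pixel mask.

    Parameters
    ----------
    stack : ImageStack or ndarray
        Intensity image.
    method : {"otsu", "fixed"}
        ``otsu`` picks a global threshold from the intensity histogram;
        ``fixed`` applies ``fixed_threshold`` as given.
    fixed_threshold : float, optional
        Required iff ``method == "fixed"``.
    smooth_sigma : float
        Gaussian pre-smoothing sigma in voxels (0 disables).  When active,
        thresholding is applied to the smoothed image.

    Returns
    -------
    ForegroundMask
        Voxels with (working) intensity strictly above the threshold.
    """
    data = stack.data if isinstance(stack, ImageStack) else np.asarray(stack)
    if data.size == 0:
        raise EmptyMaskError("empty image")
    work = data.astype(float)
    if smooth_sigma > 0:
        work = ndi.gaussian_filter(work, smooth_sigma)
    if method == "otsu":
        if fixed_threshold is not None:
            raise ValueError("fixed_threshold is only valid with method='fixed'")
        if work.min() == work.max():
            raise DegenerateImageError(
                "degenerate histogram: constant image, Otsu threshold undefined"
            )
        threshold = float(threshold_otsu(work))
    elif method == "fixed":
        if fixed_threshold is None:
            raise ValueError("method='fixed' requires fixed_threshold")
        threshold = float(fixed_threshold)
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    mask = work > threshold
    if not mask.any():
        raise NoForegroundError(f"no foreground above threshold {threshold}")
    return ForegroundMask(mask=mask, threshold_used=threshold, method=method,
                          smooth_sigma=float(smooth_sigma))


def _regularize(mask: np.ndarray) -> np.ndarray:
    """Pit and hole filling used only for center/radius estimation.

    Surface pits and interior unstained voxels (noise drop-outs, lumens)
    would otherwise collapse the distance-transform depth estimate.  The
    operation is fill-only — a background voxel is added when at least
    half of its neighbors are foreground, then enclosed cavities are
    filled — so thin structures are never eroded, and the classification
    mask itself is never altered.
    """
    kernel = np.ones((3,) * mask.ndim, dtype=np.uint8)
    neighbor_counts = ndi.correlate(mask.astype(np.uint8), kernel, mode="constant") - mask
    half_neighbors = (kernel.size - 1) // 2
    filled = mask | (neighbor_counts >= half_neighbors)
    return ndi.binary_fill_holes(filled)


def locate_core(mask, spacing=None, warn_multiple: bool = True) -> tuple[tuple[int, ...], float]:
    """Spheroid center voxel and maximal inscribed-ball radius.

    The Euclidean distance transform is computed on a regularized copy of
    the mask; the center is the EDT argmax restricted to actual foreground
    voxels of the largest regularized component (ties broken by the lowest
    lexicographic index) and the radius is the EDT value there, in
    physical units.
    """
    m = _as_bool_mask(mask)
    if not m.any():
        raise EmptyMaskError("empty mask: cannot locate a spheroid core")
    regular = _regularize(m)
    structure = np.ones((3,) * m.ndim, dtype=bool)
    labeled, n_components = ndi.label(regular, structure=structure)
    if n_components > 1 and warn_multiple:
        logger.warning(
            "foreground has %d connected components; using the largest", n_components
        )
    sizes = np.bincount(labeled.ravel())[1:]
    largest = int(np.argmax(sizes)) + 1
    edt = ndi.distance_transform_edt(regular, sampling=spacing)
    candidates = m & (labeled == largest)
    if not candidates.any():  # largest blob is pure fill artifact; fall back
        candidates = m
    edt_in_component = np.where(candidates, edt, -1.0)
    flat_index = int(np.argmax(edt_in_component))  # first occurrence = lexicographic tie-break
    center = tuple(int(c) for c in np.unravel_index(flat_index, m.shape))
    radius = float(edt_in_component.ravel()[flat_index])
    return center, radius


def inscribed_core_mask(mask, center, radius: float, spacing=None) -> np.ndarray:
    """Connected foreground region strictly inside a ball around ``center``.

    The strict ``<`` comparison keeps outgrowth voxels that sit exactly at
    the inscribed radius (e.g. the first voxel of a thin sprout) out of the
    core.  Connectivity is the full neighborhood of the array rank.
    """
    m = _as_bool_mask(mask)
    dist = _distance_grid(m.shape, center, spacing)
    candidate = m & (dist < radius)
    candidate[tuple(center)] = m[tuple(center)]
    structure = np.ones((3,) * m.ndim, dtype=bool)
    labeled, _ = ndi.label(candidate, structure=structure)
    return labeled == labeled[tuple(center)]


def estimate_core(mask, spacing=None) -> CoreEstimate:
    """Locate the spheroid center and core region in a foreground mask.

    One spheroid per field is the assay design; if the mask holds several
    blobs the largest is used and a warning is logged.
    """
    m = _as_bool_mask(mask)
    center, radius = locate_core(m, spacing)
    core_mask = inscribed_core_mask(m, center, radius, spacing)
    return CoreEstimate(center=center, core_radius_est=radius, core_mask=core_mask)
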