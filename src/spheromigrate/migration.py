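"""Collective vs single-cell migration quantification.

The classification rule is purely topological: every stained voxel that is
part of the connected network containing the spheroid center belongs to
collective migration (multicellular sprouts that stayed attached to the
spheroid body), every residual stained voxel to single-cell migration
(detached, mesenchymally migrating cells).  Migration distance is the
Euclidean physical distance of a voxel from the spheroid center (or from
the core surface in ``surface`` mode), displayed as a per-class histogram
of pixel counts over distance bins.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .io import ImageStack
from .segmentation import (
    CoreEstimate,
    ForegroundMask,
    estimate_core,
    segment_foreground,
)

__all__ = [
    "MigrationClass",
    "MigrationLabels",
    "MigrationHistogram",
    "MigrationSummary",
    "QuantifyResult",
    "classify_migration",
    "filter_small_singles",
    "radial_distances",
    "migration_histogram",
    "summarize_migration",
    "quantify_stack",
    "quantify_panel",
]


class MigrationClass(IntEnum):
    """Per-voxel label classes."""

    BACKGROUND = 0
    CORE = 1
    COLLECTIVE = 2
    SINGLE = 3


#: connectivity flag -> scipy structure rank, per array rank
_CONNECTIVITY_RANK = {2: {4: 1, 8: 2}, 3: {6: 1, 18: 2, 26: 3}}


def _structure(ndim: int, connectivity: int | None):
    if ndim not in _CONNECTIVITY_RANK:
        raise ValueError(f"unsupported array rank {ndim}")
    if connectivity is None:
        connectivity = 8 if ndim == 2 else 26
    try:
        rank = _CONNECTIVITY_RANK[ndim][connectivity]
    except KeyError:
        valid = sorted(_CONNECTIVITY_RANK[ndim])
        raise ValueError(
            f"connectivity {connectivity} invalid for {ndim}D; choose one of {valid}"
        ) from None
    return ndi.generate_binary_structure(ndim, rank), connectivity


@dataclass
class MigrationLabels:
    """Per-voxel migration classes under a declared connectivity."""

    labels: np.ndarray
    connectivity: int

    def class_counts(self) -> dict[str, int]:
        counts = np.bincount(self.labels.ravel(), minlength=4)
        return {cls.name.lower(): int(counts[cls]) for cls in MigrationClass}


@dataclass
class MigrationHistogram:
    """Per-class pixel counts over uniform radial distance bins.

    Bins are half-open lower-inclusive ``[k*w, (k+1)*w)``; distances below
    zero (possible in ``surface`` reference mode) land in bin 0, distances
    beyond an explicit ``max_dist`` in the last bin, so counts always sum
    to the labeled voxel count per class.
    """

    bin_edges: np.ndarray
    collective_counts: np.ndarray
    single_counts: np.ndarray
    reference: str = "center"

    def as_frame(self) -> pd.DataFrame:
        edges = np.asarray(self.bin_edges, dtype=float)
        return pd.DataFrame(
            {
                "bin_lo": edges[:-1],
                "bin_hi": edges[1:],
                "collective_pixels": np.asarray(self.collective_counts, dtype=np.int64),
                "single_pixels": np.asarray(self.single_counts, dtype=np.int64),
            }
        )


@dataclass
class MigrationSummary:
    """Scalar per-image migration metrics.

    Distance statistics are ``None`` when the corresponding class is empty;
    ``collective_fraction`` is ``None`` when there is no outgrowth at all.
    """

    n_core: int
    n_collective: int
    n_single: int
    max_dist_collective: float | None = None
    mean_dist_collective: float | None = None
    max_dist_single: float | None = None
    mean_dist_single: float | None = None
    collective_fraction: float | None = None


def classify_migration(mask, core: CoreEstimate, connectivity: int | None = None) -> MigrationLabels:
    """Split the foreground into core / collective / single-cell voxels.

    The connected component (under ``connectivity``) containing the
    spheroid center, minus the core region, is collective migration; all
    foreground voxels outside that component are single-cell migration.
    """
    m = mask.mask if isinstance(mask, ForegroundMask) else np.asarray(mask, dtype=bool)
    structure, connectivity = _structure(m.ndim, connectivity)
    if not m[tuple(core.center)]:
        raise ValueError("spheroid center does not lie on the foreground")
    labeled, _ = ndi.label(m, structure=structure)
    network = labeled == labeled[tuple(core.center)]
    labels = np.zeros(m.shape, dtype=np.uint8)
    labels[m] = MigrationClass.SINGLE
    labels[network] = MigrationClass.COLLECTIVE
    labels[network & core.core_mask] = MigrationClass.CORE
    return MigrationLabels(labels=labels, connectivity=connectivity)


def filter_small_singles(labels: MigrationLabels, min_size: int = 1) -> MigrationLabels:
    """Drop single-cell objects smaller than ``min_size`` voxels to background.

    With the default ``min_size=1`` this is a no-op; larger values suppress
    speckle false positives that survive thresholding of noisy images.
    """
    if min_size <= 1:
        return labels
    single = labels.labels == MigrationClass.SINGLE
    if not single.any():
        return labels
    structure, _ = _structure(single.ndim, labels.connectivity)
    labeled, n = ndi.label(single, structure=structure)
    if n == 0:
        return labels
    sizes = np.bincount(labeled.ravel())
    small = sizes < min_size
    small[0] = False
    out = labels.labels.copy()
    out[small[labeled]] = MigrationClass.BACKGROUND
    return MigrationLabels(labels=out, connectivity=labels.connectivity)


def radial_distances(
    labels: MigrationLabels,
    core: CoreEstimate,
    spacing=None,
    reference: str = "center",
) -> dict[str, np.ndarray]:
    """Per-voxel migration distances for the collective and single classes.

    Distance is the Euclidean physical distance from the voxel to the
    spheroid center; with ``reference="surface"`` the estimated core radius
    is subtracted (values may be negative just inside the core surface).
    """
    if reference not in ("center", "surface"):
        raise ValueError(f"reference must be 'center' or 'surface', got {reference!r}")
    arr = labels.labels
    spacing_v = np.ones(arr.ndim) if spacing is None else np.asarray(spacing, dtype=float)
    center = np.asarray(core.center, dtype=float)
    out: dict[str, np.ndarray] = {}
    for cls, name in ((MigrationClass.COLLECTIVE, "collective"), (MigrationClass.SINGLE, "single")):
        coords = np.argwhere(arr == cls)
        d = np.sqrt((((coords - center) * spacing_v) ** 2).sum(axis=1))
        if reference == "surface":
            d = d - core.core_radius_est
        out[name] = d
    return out


def migration_histogram(
    collective_distances,
    single_distances,
    bin_width: float = 10.0,
    max_dist: float | None = None,
    reference: str = "center",
) -> MigrationHistogram:
    """Bin per-voxel migration distances into a per-class histogram."""
    if bin_width <= 0:
        raise ValueError(f"bin_width must be positive, got {bin_width}")
    coll = np.clip(np.asarray(collective_distances, dtype=float), 0.0, None)
    single = np.clip(np.asarray(single_distances, dtype=float), 0.0, None)
    if max_dist is not None:
        n_bins = max(1, math.ceil(max_dist / bin_width))
    elif coll.size + single.size:
        top = max(coll.max() if coll.size else 0.0, single.max() if single.size else 0.0)
        n_bins = int(top // bin_width) + 1
    else:
        n_bins = 0
    edges = np.arange(n_bins + 1, dtype=float) * bin_width

    def _count(d: np.ndarray) -> np.ndarray:
        if n_bins == 0:
            return np.zeros(0, dtype=np.int64)
        idx = np.minimum((d // bin_width).astype(np.int64), n_bins - 1)
        return np.bincount(idx, minlength=n_bins).astype(np.int64)

    return MigrationHistogram(
        bin_edges=edges,
        collective_counts=_count(coll),
        single_counts=_count(single),
        reference=reference,
    )


def summarize_migration(labels: MigrationLabels, distances: dict[str, np.ndarray]) -> MigrationSummary:
    """Reduce labels and distances to per-image scalar metrics."""
    counts = labels.class_counts()
    coll = np.asarray(distances["collective"], dtype=float)
    single = np.asarray(distances["single"], dtype=float)
    n_collective, n_single = counts["collective"], counts["single"]
    total_outgrowth = n_collective + n_single
    return MigrationSummary(
        n_core=counts["core"],
        n_collective=n_collective,
        n_single=n_single,
        max_dist_collective=float(coll.max()) if coll.size else None,
        mean_dist_collective=float(coll.mean()) if coll.size else None,
        max_dist_single=float(single.max()) if single.size else None,
        mean_dist_single=float(single.mean()) if single.size else None,
        collective_fraction=(n_collective / total_outgrowth) if total_outgrowth else None,
    )


@dataclass
class QuantifyResult:
    """All artifacts of a full quantification run, for inspection."""

    stack: ImageStack
    mask: ForegroundMask
    core: CoreEstimate
    labels: MigrationLabels
    histogram: MigrationHistogram
    summary: MigrationSummary
    mode: str = "3d"
    distances: dict = field(default_factory=dict, repr=False)


def quantify_stack(
    stack: ImageStack,
    *,
    mode: str = "3d",
    threshold="otsu",
    smooth_sigma: float = 0.0,
    connectivity: int | None = None,
    bin_width: float = 10.0,
    reference: str = "center",
    min_single_size: int = 1,
    max_dist: float | None = None,
) -> QuantifyResult:
    """Run the full pipeline: segment, locate core, classify, histogram.

    Parameters
    ----------
    stack : ImageStack
        Input intensity stack.
    mode : {"3d", "mip"}
        ``mip`` first collapses the stack to 2D by maximum-intensity
        projection; ``3d`` works on the full volume.
    threshold : "otsu" or float
        Global threshold method; a number selects a fixed threshold.
    smooth_sigma : float
        Gaussian pre-smoothing sigma in voxels before thresholding.
    connectivity : int, optional
        Voxel connectivity for the network classification
        (6/18/26 in 3D, 4/8 in 2D); defaults to the most permissive.
    bin_width : float
        Histogram bin width in physical distance units.
    reference : {"center", "surface"}
        Distance reference for histograms and summary statistics.
    min_single_size : int
        Minimum voxel count for a single-cell object; smaller objects are
        dropped to background (1 disables the filter).
    """
    mode = mode.lower()
    if mode not in ("3d", "mip"):
        raise ValueError(f"mode must be '3d' or 'mip', got {mode!r}")
    working = stack
    if mode == "mip" and stack.data.shape[0] > 1:
        working = ImageStack(
            stack.data.max(axis=0, keepdims=True),
            spacing=stack.spacing,
            name=(stack.name + ":mip") if stack.name else "mip",
        )
    if isinstance(threshold, str) and threshold == "otsu":
        fg = segment_foreground(working, method="otsu", smooth_sigma=smooth_sigma)
    else:
        fg = segment_foreground(
            working, method="fixed", fixed_threshold=float(threshold), smooth_sigma=smooth_sigma
        )
    core = estimate_core(fg, spacing=working.spacing)
    labels = classify_migration(fg, core, connectivity=connectivity)
    labels = filter_small_singles(labels, min_single_size)
    distances = radial_distances(labels, core, spacing=working.spacing, reference=reference)
    hist = migration_histogram(
        distances["collective"], distances["single"],
        bin_width=bin_width, max_dist=max_dist, reference=reference,
    )
    summary = summarize_migration(labels, distances)
    return QuantifyResult(
        stack=working, mask=fg, core=core, labels=labels,
        histogram=hist, summary=summary, mode=mode, distances=distances,
    )


def quantify_panel(images, **options) -> pd.DataFrame:
    """Quantify a panel of named images into one tidy table.

    ``images`` maps condition name to :class:`ImageStack` (or to
    ``(ImageStack, ...)`` tuples whose first element is the stack, as
    produced by the synthetic condition-panel generator).  Extra keyword
    arguments are forwarded to :func:`quantify_stack`.
    """
    rows = []
    for name, item in images.items():
        stack = item[0] if isinstance(item, tuple) else item
        result = quantify_stack(stack, **options)
        row = {"condition": name}
        row.update(vars(result.summary))
        rows.append(row)
    return pd.DataFrame(rows)
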