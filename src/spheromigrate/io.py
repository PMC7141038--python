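"""Image and tabular input/output.

Single-channel grayscale TIFFs come in (one page = 2D, multipage = z-stack);
histograms leave as CSV and per-image summaries as JSON.  All arrays use the
axis order (plane, row, column); a 2D image is carried as a stack with a
single plane so every downstream operation has one code path.
"""
from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .exceptions import MultichannelImageError, UnsupportedImageError

__all__ = [
    "ImageStack",
    "read_stack",
    "write_stack",
    "write_histogram_csv",
    "read_histogram_csv",
    "write_summary_json",
    "read_summary_json",
]


@dataclass
class ImageStack:
    """A scalar intensity volume with physical voxel spacing.

    Parameters
    ----------
    data : ndarray
        Intensity array ordered (plane, row, column).  A 2D array is
        promoted to shape ``(1, rows, columns)``.
    spacing : tuple of float
        Physical size of one voxel along each axis (length units / voxel).
    name : str
        Source identifier used in logs and output file names.
    """

    data: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    name: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.ndim == 2:
            data = data[np.newaxis]
        if data.ndim != 3:
            raise UnsupportedImageError(
                f"expected a 2D image or 3D stack, got {data.ndim} dimensions"
            )
        spacing = tuple(float(s) for s in self.spacing)
        if len(spacing) == 2:
            spacing = (1.0,) + spacing
        if len(spacing) != 3:
            raise ValueError("spacing must have one entry per axis (plane, row, column)")
        if any(s <= 0 for s in spacing):
            raise ValueError(f"spacing entries must be positive, got {spacing}")
        if not np.issubdtype(data.dtype, np.number):
            raise UnsupportedImageError(f"unsupported sample format {data.dtype}")
        if np.issubdtype(data.dtype, np.floating):
            if not np.isfinite(data).all():
                raise ValueError("intensities must be finite")
            if (data < 0).any():
                raise ValueError("intensities must be non-negative")
        self.data = data
        self.spacing = spacing

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def is_2d(self) -> bool:
        return self.data.shape[0] == 1


def _spacing_from_tiff(tf: tifffile.TiffFile) -> tuple[float, float, float]:
    """Best-effort voxel spacing from ImageJ metadata / resolution tags."""
    sz = sy = sx = 1.0
    meta = tf.imagej_metadata
    if meta and meta.get("spacing"):
        try:
            sz = float(meta["spacing"])
        except (TypeError, ValueError):
            pass
    page = tf.pages[0]
    for tag_name, which in (("XResolution", "x"), ("YResolution", "y")):
        tag = page.tags.get(tag_name)
        if tag is None:
            continue
        num, den = tag.value
        if num:
            value = den / num
            if which == "x":
                sx = value
            else:
                sy = value
    return (sz, sy, sx)


def read_stack(path, spacing_override=None) -> ImageStack:
    """Read a single-channel grayscale TIFF as an :class:`ImageStack`.

    A one-page file becomes a stack with a single plane; a multipage file a
    z-stack.  Voxel spacing is taken from ImageJ metadata / resolution tags
    when present, defaults to 1.0 per axis and can be overridden.

    Raises
    ------
    FileNotFoundError
        If ``path`` does not exist.
    MultichannelImageError
        For RGB(A) or multi-channel input; channel selection is the
        caller's job upstream.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such image file: {path}")
    with tifffile.TiffFile(path) as tf:
        series = tf.series[0]
        axes = series.axes.upper()
        if "S" in axes or "C" in axes:
            raise MultichannelImageError(
                f"multichannel input ({path}, axes {axes!r}); a single grayscale channel is required"
            )
        data = series.asarray()
        spacing = _spacing_from_tiff(tf)
    if data.ndim not in (2, 3):
        raise UnsupportedImageError(
            f"cannot interpret {path} with axes {axes!r} as a grayscale image or z-stack"
        )
    if spacing_override is not None:
        spacing = tuple(float(s) for s in spacing_override)
    return ImageStack(data, spacing=spacing, name=path.stem)


def write_stack(stack: ImageStack, path) -> None:
    """Write an :class:`ImageStack` as an ImageJ-compatible ZYX TIFF."""
    path = Path(path)
    data = stack.data
    imagej = data.dtype in (np.uint8, np.uint16)
    sz, sy, sx = stack.spacing
    kwargs = {}
    if imagej:
        kwargs = {
            "imagej": True,
            "resolution": (1.0 / sx, 1.0 / sy),
            "metadata": {"spacing": sz, "axes": "ZYX", "unit": "pixel"},
        }
    tifffile.imwrite(path, data, **kwargs)


# -- tabular output ---------------------------------------------------------

_HIST_COLUMNS = ["bin_lo", "bin_hi", "collective_pixels", "single_pixels"]


def write_histogram_csv(hist, path) -> None:
    """Write a migration histogram as CSV.

    Columns are ``bin_lo, bin_hi, collective_pixels, single_pixels``, one
    row per distance bin; counts are written as integers so a round trip
    through :func:`read_histogram_csv` is bit-exact.
    """
    edges = np.asarray(hist.bin_edges, dtype=float)
    frame = pd.DataFrame(
        {
            "bin_lo": edges[:-1],
            "bin_hi": edges[1:],
            "collective_pixels": np.asarray(hist.collective_counts, dtype=np.int64),
            "single_pixels": np.asarray(hist.single_counts, dtype=np.int64),
        },
        columns=_HIST_COLUMNS,
    )
    frame.to_csv(path, index=False)


def read_histogram_csv(path, reference: str = "center"):
    """Read a histogram CSV written by :func:`write_histogram_csv`."""
    from .migration import MigrationHistogram

    frame = pd.read_csv(path)
    missing = [c for c in _HIST_COLUMNS if c not in frame.columns]
    if missing:
        raise ValueError(f"histogram CSV {path} lacks columns {missing}")
    if len(frame) == 0:
        edges = np.array([0.0])
        counts = np.zeros(0, dtype=np.int64)
        return MigrationHistogram(edges, counts, counts.copy(), reference=reference)
    edges = np.concatenate([frame["bin_lo"].to_numpy(float), frame["bin_hi"].to_numpy(float)[-1:]])
    return MigrationHistogram(
        edges,
        frame["collective_pixels"].to_numpy(np.int64),
        frame["single_pixels"].to_numpy(np.int64),
        reference=reference,
    )


def write_summary_json(summary, path) -> None:
    """Write a :class:`~spheromigrate.migration.MigrationSummary` as JSON."""
    payload = dataclasses.asdict(summary)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_summary_json(path):
    """Read a summary JSON written by :func:`write_summary_json`."""
    from .migration import MigrationSummary

    with open(path) as fh:
        payload = json.load(fh)
    return MigrationSummary(**payload)
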