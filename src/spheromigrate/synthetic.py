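"""Seeded synthetic spheroid-outgrowth images with voxel-level ground truth.

The generator emulates the imaging of an f-actin-stained microtissue
outgrowth assay: a bright, roughly spherical spheroid core (a several-
hundred-cell microtissue), contiguous multicellular sprouts emanating from
it (collective migration), scattered isolated cells (single-cell
migration), additive Gaussian noise on a two-level intensity image and
optional Gaussian PSF blur.  Every image comes with exact pre-noise labels
so downstream segmentation and classification can be tested without any
acquired data.

Output is a pure function of :class:`SpheroidParams`: the same parameters
(including seed) give bit-identical arrays.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi

from .exceptions import SpheroidGeometryError
from .io import ImageStack
from .migration import MigrationClass
from .segmentation import inscribed_core_mask, locate_core

__all__ = [
    "SpheroidParams",
    "GroundTruth",
    "generate_spheroid_stack",
    "generate_condition_panel",
]

_DTYPES = {"uint8": (np.uint8, 255.0), "uint16": (np.uint16, 65535.0)}

_MAX_ATTEMPTS = 200


@dataclass(frozen=True)
class SpheroidParams:
    """Generative parameters for one synthetic spheroid image.

    All geometry is expressed in voxels; ``spacing`` only affects the
    physical units of the ground-truth core labeling and downstream
    distance measurements.  Defaults describe a 128x128 field with a
    16-plane confocal-like slab holding one spheroid with a handful of
    sprouts and scattered single cells at realistic contrast.

    Attributes
    ----------
    shape : tuple of int
        Voxel dimensions per axis, ordered (plane, row, column).  Use a
        leading 1 for 2D generation (same code path, singleton axis).
    spacing : tuple of float
        Physical size per axis (length units / voxel).
    core_radius : float
        Spheroid core radius in voxels.
    center : tuple of int or "auto"
        Spheroid center voxel; ``"auto"`` places it at the image center.
    n_sprouts, sprout_length_mean, sprout_length_sd, sprout_width :
        Number of collective sprouts, their length distribution (voxels,
        normal, truncated at 1) and their thickness (voxels, >= 1).
    n_single, single_radius, single_dist_range :
        Number of isolated single cells, their radius (voxels) and the
        admissible range of their center distance from the spheroid center.
    fg_intensity, bg_intensity : float
        Mean foreground / background grey levels (fg must exceed bg).
    noise_sd : float
        Additive Gaussian noise standard deviation (grey levels).
    psf_sigma : float
        Gaussian blur sigma in voxels applied after noise (0 disables).
    dtype : {"uint8", "uint16"}
        Output sample type; intensities are clipped to its range.
    guarantee_isolation : bool
        Enforce >= 2-voxel clearance between each single cell and the
        core+sprout network (and between single cells), so ground truth
        connectivity is unambiguous.
    seed : int
        RNG seed; generation is fully deterministic given the parameters.
    """

    shape: tuple[int, int, int] = (16, 128, 128)
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    core_radius: float = 6.0
    center: tuple[int, int, int] | str = "auto"
    n_sprouts: int = 5
    sprout_length_mean: float = 20.0
    sprout_length_sd: float = 4.0
    sprout_width: float = 3.0
    n_single: int = 10
    single_radius: float = 2.0
    single_dist_range: tuple[float, float] = (30.0, 50.0)
    fg_intensity: float = 200.0
    bg_intensity: float = 20.0
    noise_sd: float = 10.0
    psf_sigma: float = 0.0
    dtype: str = "uint8"
    guarantee_isolation: bool = True
    seed: int = 0

    def resolved_center(self) -> tuple[int, ...]:
        if isinstance(self.center, str):
            if self.center != "auto":
                raise ValueError(f"center must be coordinates or 'auto', got {self.center!r}")
            return tuple(int(n) // 2 for n in self.shape)
        return tuple(int(c) for c in self.center)

    def validate(self) -> None:
        if len(self.shape) != 3 or any(int(n) <= 0 for n in self.shape):
            raise SpheroidGeometryError(f"shape must be 3 positive extents, got {self.shape}")
        if any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be positive, got {self.spacing}")
        if self.core_radius <= 0:
            raise SpheroidGeometryError("core_radius must be > 0")
        if self.sprout_width < 1:
            raise SpheroidGeometryError("sprout_width must be >= 1 voxel")
        if self.n_sprouts < 0 or self.n_single < 0:
            raise ValueError("object counts must be non-negative")
        if self.single_radius <= 0:
            raise SpheroidGeometryError("single_radius must be > 0")
        center = self.resolved_center()
        for axis, (n, c) in enumerate(zip(self.shape, center)):
            if not (0 <= c < n):
                raise SpheroidGeometryError(f"center {center} outside shape {self.shape}")
            # singleton axes carry planar geometry; no radial fit check there
            if n > 1 and (c - self.core_radius < 0 or c + self.core_radius > n - 1):
                raise SpheroidGeometryError(
                    f"core of radius {self.core_radius} at {center} does not fit "
                    f"axis {axis} of extent {n}"
                )
        lo, hi = self.single_dist_range
        if not (0 < lo <= hi):
            raise SpheroidGeometryError(f"invalid single_dist_range {self.single_dist_range}")
        if self.n_single and lo <= self.core_radius:
            raise SpheroidGeometryError(
                "single_dist_range.min must exceed core_radius so single cells "
                "cannot be seeded inside the spheroid core"
            )
        if self.fg_intensity <= self.bg_intensity:
            raise ValueError("fg_intensity must exceed bg_intensity")
        if self.noise_sd < 0 or self.psf_sigma < 0:
            raise ValueError("noise_sd and psf_sigma must be non-negative")
        if self.dtype not in _DTYPES:
            raise ValueError(f"dtype must be one of {sorted(_DTYPES)}")


@dataclass
class GroundTruth:
    """Exact pre-noise labels and bookkeeping for a generated image."""

    labels: np.ndarray
    true_counts: dict[str, int]
    true_center: tuple[int, ...]
    inscribed_radius: float

    def foreground_count(self) -> int:
        return int(sum(v for k, v in self.true_counts.items() if k != "background"))


def _ball(shape, center, radius: float) -> np.ndarray:
    grids = np.indices(shape, dtype=float)
    d2 = np.zeros(shape)
    for g, c in zip(grids, center):
        d2 += (g - c) ** 2
    return d2 <= radius**2


def _capsule(shape, p0, p1, radius: float) -> np.ndarray:
    """Voxels within ``radius`` of the segment p0-p1 (cylinder + caps)."""
    p0 = np.asarray(p0, dtype=float)
    p1 = np.asarray(p1, dtype=float)
    v = p1 - p0
    vv = float(v @ v)
    grids = np.indices(shape, dtype=float)
    coords = np.stack([g.ravel() for g in grids], axis=1)
    if vv == 0:
        d2 = ((coords - p0) ** 2).sum(axis=1)
    else:
        t = np.clip((coords - p0) @ v / vv, 0.0, 1.0)
        proj = p0 + t[:, None] * v
        d2 = ((coords - proj) ** 2).sum(axis=1)
    return (d2 <= radius**2).reshape(shape)


def _sprout_direction(rng, shape, center, reach: float, margin: float) -> np.ndarray:
    """Random outward unit vector whose tip stays inside the volume.

    Directions are sampled isotropically over non-singleton axes and
    rejected until the sprout tip fits; in thin slabs this keeps sprouts
    essentially in-plane, as a finite imaging volume would.
    """
    singleton = [n == 1 for n in shape]
    for _ in range(_MAX_ATTEMPTS):
        u = rng.normal(size=len(shape))
        u[singleton] = 0.0
        norm = np.linalg.norm(u)
        if norm < 1e-9:
            continue
        u /= norm
        tip = np.asarray(center, dtype=float) + reach * u
        ok = True
        for axis, n in enumerate(shape):
            if singleton[axis]:
                continue
            if not (margin <= tip[axis] <= n - 1 - margin):
                ok = False
                break
        if ok:
            return u
    raise SpheroidGeometryError(
        f"sprout of reach {reach:.1f} voxels cannot fit inside shape {tuple(shape)}"
    )


def _place_singles(rng, params: SpheroidParams, network: np.ndarray, center) -> np.ndarray:
    shape = tuple(int(n) for n in params.shape)
    r = params.single_radius
    lo, hi = params.single_dist_range
    singles = np.zeros(shape, dtype=bool)
    accepted: list[np.ndarray] = []
    clearance = None
    if params.guarantee_isolation:
        # distance of every voxel to the nearest network voxel, in voxels
        clearance = ndi.distance_transform_edt(~network)
    attempts = 0
    budget = _MAX_ATTEMPTS * max(1, params.n_single)
    while len(accepted) < params.n_single:
        attempts += 1
        if attempts > budget:
            raise SpheroidGeometryError(
                f"could not place {params.n_single} isolated single cells at "
                f"distances {params.single_dist_range} inside shape {shape}; "
                "the admissible shell is too small or too crowded"
            )
        pos = np.array(
            [
                0.0 if n == 1 else rng.uniform(r + 1, n - 2 - r)
                for n in shape
            ]
        )
        d = float(np.linalg.norm(pos - np.asarray(center, dtype=float)))
        if not (lo <= d <= hi):
            continue
        if params.guarantee_isolation:
            # +1 slack for rounding the continuous center to a voxel
            if clearance[tuple(np.round(pos).astype(int))] < r + 3:
                continue
            if any(np.linalg.norm(pos - q) < 2 * r + 3 for q in accepted):
                continue
        accepted.append(pos)
        singles |= _ball(shape, pos, r)
    return singles


def generate_spheroid_stack(params: SpheroidParams) -> tuple[ImageStack, GroundTruth]:
    """Generate one synthetic spheroid-outgrowth image with ground truth.

    Returns
    -------
    (ImageStack, GroundTruth)
        The noisy intensity image and the exact pre-noise class labels
        (background / core / collective / single), voxel counts per class
        and the true center.  With ``guarantee_isolation`` every single
        cell is a connected component separate from the core+sprout
        network under any standard connectivity.
    """
    params.validate()
    shape = tuple(int(n) for n in params.shape)
    center = params.resolved_center()
    rng = np.random.default_rng(params.seed)

    network = _ball(shape, center, params.core_radius)
    for _ in range(params.n_sprouts):
        length = max(1.0, float(rng.normal(params.sprout_length_mean, params.sprout_length_sd)))
        reach = params.core_radius + length
        direction = _sprout_direction(
            rng, shape, center, reach, margin=params.sprout_width / 2 + 1
        )
        tip = np.asarray(center, dtype=float) + reach * direction
        network |= _capsule(shape, center, tip, params.sprout_width / 2)

    singles = np.zeros(shape, dtype=bool)
    if params.n_single:
        singles = _place_singles(rng, params, network, center)

    foreground = network | singles

    # Core labeling mirrors the quantifier's convention: the connected
    # foreground strictly inside the maximal inscribed ball at the center.
    _, rho = locate_core(foreground, params.spacing, warn_multiple=False)
    core_label = inscribed_core_mask(foreground, center, rho, params.spacing)

    labels = np.zeros(shape, dtype=np.uint8)
    labels[foreground] = MigrationClass.SINGLE
    labels[network] = MigrationClass.COLLECTIVE
    labels[core_label] = MigrationClass.CORE

    counts = np.bincount(labels.ravel(), minlength=4)
    true_counts = {cls.name.lower(): int(counts[cls]) for cls in MigrationClass}

    np_dtype, dtype_max = _DTYPES[params.dtype]
    image = np.full(shape, params.bg_intensity, dtype=float)
    image[foreground] = params.fg_intensity
    if params.noise_sd > 0:
        image += rng.normal(0.0, params.noise_sd, size=shape)
    if params.psf_sigma > 0:
        image = ndi.gaussian_filter(image, params.psf_sigma)
    image = np.clip(np.rint(image), 0, dtype_max).astype(np_dtype)

    stack = ImageStack(image, spacing=params.spacing, name=f"synthetic-seed{params.seed}")
    truth = GroundTruth(
        labels=labels,
        true_counts=true_counts,
        true_center=center,
        inscribed_radius=rho,
    )
    return stack, truth


def _derived_seed(base_seed: int, index: int) -> int:
    state = np.random.SeedSequence(entropy=(int(base_seed), int(index))).generate_state(1)[0]
    return int(state % (2**31))


def generate_condition_panel(base: SpheroidParams, condition_specs):
    """Generate one seeded image per experimental condition.

    ``condition_specs`` maps condition name to a dict of
    :class:`SpheroidParams` field overrides (or is a list of
    ``(name, overrides)`` pairs).  Seeds are derived deterministically from
    ``base.seed`` and the condition index unless an override sets one.

    Returns
    -------
    dict
        Condition name -> ``(ImageStack, GroundTruth)`` in input order.
    """
    if hasattr(condition_specs, "items"):
        pairs = list(condition_specs.items())
    else:
        pairs = [(name, dict(ov)) for name, ov in condition_specs]
        names = [name for name, _ in pairs]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate condition names: {dupes}")
    panel = {}
    for index, (name, overrides) in enumerate(pairs):
        fields = {"seed": _derived_seed(base.seed, index)}
        fields.update(overrides)
        panel[name] = generate_spheroid_stack(dataclasses.replace(base, **fields))
    return panel
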