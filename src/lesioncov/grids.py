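"""Voxel-space bookkeeping shared by every analysis stage.

A :class:`VoxelGrid` couples a 3-D array shape with millimetre geometry and a
set of named boolean masks (brain, cortex, subcortical, per-tract streamline
densities).  All spatial maps (:class:`BrainMap`), per-subject lesion masks
(:class:`LesionMask`) and the subjects-by-voxels matrix the decomposition
consumes (:class:`LesionStack`) reference a grid and a mask domain, so voxel
ordering and geometry are defined in exactly one place.

Conventions
-----------
* Voxel indices are 0-based; distances are between voxel centres in mm.
* A map's ``values`` vector follows C-order over the ``True`` voxels of its
  domain mask.
* The midline is the centre plane of ``midline_axis``: index ``i`` mirrors to
  ``shape[axis] - 1 - i``, and "left" means ``i < shape[axis] / 2``.  This is
  the convention for synthetic grids; grids read from NIfTI keep their affine
  so real data can place the midline at x = 0.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
from scipy.ndimage import gaussian_filter

logger = logging.getLogger(__name__)

#: full width at half maximum of a Gaussian, in units of sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


class GridError(ValueError):
    """Raised when a volume's geometry does not match the expected grid."""


class ValidationError(ValueError):
    """Raised when data violate a domain-type invariant."""


@dataclass
class VoxelGrid:
    shape: tuple[int, int, int]
    voxel_size_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    midline_axis: int = 0
    masks: dict[str, np.ndarray] = field(default_factory=dict)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.shape = tuple(int(s) for s in self.shape)
        self.voxel_size_mm = tuple(float(v) for v in self.voxel_size_mm)
        if any(v <= 0 for v in self.voxel_size_mm):
            raise ValidationError("voxel sizes must be positive")
        for name, m in self.masks.items():
            self.masks[name] = self._check_mask(name, m)

    def _check_mask(self, name: str, m: np.ndarray) -> np.ndarray:
        m = np.asarray(m, dtype=bool)
        if m.shape != self.shape:
            raise GridError(f"mask {name!r} shape {m.shape} != grid shape {self.shape}")
        return m

    def add_mask(self, name: str, m: np.ndarray) -> None:
        self.masks[name] = self._check_mask(name, m)

    def mask(self, name: str) -> np.ndarray:
        if name not in self.masks:
            raise KeyError(f"grid has no mask {name!r}")
        return self.masks[name]

    def n_voxels(self, domain: str) -> int:
        return int(self.mask(domain).sum())

    def mask_indices(self, domain: str) -> np.ndarray:
        """Flat C-order indices of the domain's voxels."""
        return np.flatnonzero(self.mask(domain))

    def coords_mm(self, domain: str) -> np.ndarray:
        """(V, 3) voxel-centre coordinates in mm for the domain's voxels."""
        ijk = np.argwhere(self.mask(domain)).astype(float)
        return ijk * np.asarray(self.voxel_size_mm) + np.asarray(self.origin_mm)

    def mirror(self, volume: np.ndarray) -> np.ndarray:
        """Reflect a volume across the midline plane."""
        return np.flip(volume, axis=self.midline_axis)

    def left_hemisphere(self) -> np.ndarray:
        """Boolean volume, True where the voxel lies left of the midline."""
        ax = self.midline_axis
        idx = np.arange(self.shape[ax])
        half = idx < self.shape[ax] / 2.0
        shp = [1, 1, 1]
        shp[ax] = self.shape[ax]
        return np.broadcast_to(half.reshape(shp), self.shape).copy()

    def default_affine(self) -> np.ndarray:
        if self.affine is not None:
            return self.affine
        aff = np.diag(list(self.voxel_size_mm) + [1.0])
        aff[:3, 3] = self.origin_mm
        return aff


@dataclass
class BrainMap:
    """One real value per voxel of a named grid domain."""

    grid: VoxelGrid
    domain: str
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float).ravel()
        n = self.grid.n_voxels(self.domain)
        if self.values.size != n:
            raise ValidationError(
                f"value count {self.values.size} != domain {self.domain!r} size {n}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("BrainMap values must be finite")

    def to_volume(self, fill: float = 0.0) -> np.ndarray:
        vol = np.full(self.grid.shape, fill, dtype=float)
        vol[self.grid.mask(self.domain)] = self.values
        return vol

    @classmethod
    def from_volume(cls, grid: VoxelGrid, domain: str, volume: np.ndarray) -> "BrainMap":
        return cls(grid, domain, np.asarray(volume, dtype=float)[grid.mask(domain)])

    def with_values(self, values: np.ndarray) -> "BrainMap":
        return BrainMap(self.grid, self.domain, values)


@dataclass
class LesionMask:
    """Binary lesion of one subject, defined on the brain mask."""

    subject_id: str
    grid: VoxelGrid
    values: np.ndarray
    hemisphere: str = "left"  # left | right | bilateral

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if not np.isin(v, (0, 1)).all():
            raise ValidationError("LesionMask values must be 0/1")
        self.values = v.astype(np.uint8).ravel()
        if self.values.size != self.grid.n_voxels("brain"):
            raise ValidationError("LesionMask must cover the brain mask domain")
        if self.values.sum() == 0:
            raise ValidationError(f"lesion mask {self.subject_id!r} is empty")

    def to_volume(self) -> np.ndarray:
        vol = np.zeros(self.grid.shape, dtype=np.uint8)
        vol[self.grid.mask("brain")] = self.values
        return vol


@dataclass
class LesionStack:
    grid: VoxelGrid
    subject_ids: list[str]
    matrix: np.ndarray  # subjects x brain voxels, binary

    def __post_init__(self) -> None:
        if self.matrix.shape != (len(self.subject_ids), self.grid.n_voxels("brain")):
            raise ValidationError("LesionStack matrix shape mismatch")
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValidationError("duplicate subject_id in LesionStack")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def frequency_map(self) -> BrainMap:
        """Voxel-wise lesion count across subjects."""
        return BrainMap(self.grid, "brain", self.matrix.sum(axis=0).astype(float))


# ---------------------------------------------------------------------------
# NIfTI IO


def read_mask(path, grid: VoxelGrid, subject_id: str | None = None) -> LesionMask:
    """Read a binary lesion mask from a NIfTI file onto ``grid``.

    Values are rounded to 0/1 (with a logged warning for non-binary input);
    any voxel outside the grid's brain mask is discarded.
    """
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.shape != grid.shape:
        raise GridError(f"{path}: shape {data.shape} != grid shape {grid.shape}")
    rounded = np.rint(data)
    if not np.allclose(data, rounded, atol=1e-6):
        logger.warning("%s: non-binary values rounded to 0/1", path)
    if not np.isin(rounded, (0, 1)).all():
        raise ValidationError(f"{path}: values not 0/1 after rounding")
    values = rounded[grid.mask("brain")].astype(np.uint8)
    if values.sum() == 0:
        raise ValidationError(f"{path}: empty lesion mask")
    sid = subject_id if subject_id is not None else str(path)
    mask = LesionMask(sid, grid, values, hemisphere="bilateral")
    mask.hemisphere = _hemisphere_of(mask)
    return mask


def write_map(bmap: BrainMap, path) -> None:
    img = nib.Nifti1Image(bmap.to_volume().astype(np.float32), bmap.grid.default_affine())
    nib.save(img, str(path))


def write_mask(mask: LesionMask, path) -> None:
    img = nib.Nifti1Image(mask.to_volume(), mask.grid.default_affine())
    nib.save(img, str(path))


def read_map(path, grid: VoxelGrid, domain: str) -> BrainMap:
    img = nib.load(str(path))
    data = np.asarray(img.get_fdata(), dtype=float)
    if data.shape != grid.shape:
        raise GridError(f"{path}: shape {data.shape} != grid shape {grid.shape}")
    return BrainMap.from_volume(grid, domain, data)


# ---------------------------------------------------------------------------
# Hemisphere folding


def _hemisphere_of(mask: LesionMask) -> str:
    vol = mask.to_volume().astype(bool)
    left = mask.grid.left_hemisphere()
    n_left = int((vol & left).sum())
    n_right = int((vol & ~left).sum())
    if n_right == 0:
        return "left"
    if n_left == 0:
        return "right"
    return "bilateral"


def fold_to_left(mask: LesionMask) -> LesionMask:
    """Mirror a right-majority lesion across the midline; unite any residual
    contralateral voxels onto the majority side by voxelwise max.

    Left-majority lesions confined to the left hemisphere are returned
    unchanged.  Exact left/right ties break toward no flip (logged).
    """
    grid = mask.grid
    vol = mask.to_volume()
    left = grid.left_hemisphere()
    n_left = int(vol[left].sum())
    n_right = int(vol[~left].sum())
    if n_right == 0:
        return LesionMask(mask.subject_id, grid, mask.values.copy(), "left")
    if n_left == n_right:
        logger.info("subject %s: exact hemisphere tie, not flipping", mask.subject_id)
    if n_right > n_left:
        vol = grid.mirror(vol)
    # fold the minority (right-side) remainder onto the left
    folded = np.maximum(vol, grid.mirror(vol))
    folded[~left] = 0
    out = folded[grid.mask("brain")]
    return LesionMask(mask.subject_id, grid, out, "left")


def fold_average(bmap: BrainMap) -> BrainMap:
    """Average a map with its mirror image (used for paired left/right tract
    density maps, which are aligned to one hemisphere and averaged)."""
    vol = bmap.to_volume()
    avg = 0.5 * (vol + bmap.grid.mirror(vol))
    return BrainMap.from_volume(bmap.grid, bmap.domain, avg)


def stack(masks: list[LesionMask]) -> LesionStack:
    if not masks:
        raise ValidationError("cannot stack zero masks")
    grid = masks[0].grid
    for m in masks:
        if m.grid is not grid and m.grid.shape != grid.shape:
            raise GridError("all masks must share one grid")
        if m.hemisphere != "left":
            raise ValidationError(f"mask {m.subject_id!r} not folded to left")
    ids = [m.subject_id for m in masks]
    matrix = np.stack([m.values for m in masks]).astype(np.uint8)
    return LesionStack(grid, ids, matrix)


# ---------------------------------------------------------------------------
# Smoothing and streamline masking


def fwhm_to_sigma(fwhm_mm: float) -> float:
    return fwhm_mm / FWHM_PER_SIGMA


def smooth(bmap: BrainMap, fwhm_mm: float) -> BrainMap:
    """Mask-aware Gaussian smoothing.

    The kernel is renormalized over in-mask voxels so that a constant map is a
    fixed point and no intensity leaks outside the mask; every output value is
    a convex combination of in-mask input values.
    """
    if fwhm_mm <= 0:
        raise ValidationError("fwhm_mm must be positive")
    grid = bmap.grid
    sigma_vox = tuple(fwhm_to_sigma(fwhm_mm) / v for v in grid.voxel_size_mm)
    m = grid.mask(bmap.domain)
    # the smoothed-mask denominator depends only on (domain, fwhm); cache it
    # on the grid since seed scans smooth thousands of maps on one domain
    cache = getattr(grid, "_smooth_cache", None)
    if cache is None:
        cache = grid._smooth_cache = {}
    key = (bmap.domain, sigma_vox)
    den = cache.get(key)
    if den is None:
        den = cache[key] = gaussian_filter(m.astype(float), sigma_vox, mode="constant")
    num = gaussian_filter(bmap.to_volume(), sigma_vox, mode="constant")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(m, num / den, 0.0)
    return BrainMap.from_volume(grid, bmap.domain, out)


def streamline_mask(density: BrainMap, fraction: float = 0.01) -> np.ndarray:
    """Indices (within the map's domain) of voxels whose streamline density
    strictly exceeds ``fraction`` of the total streamline count."""
    v = density.values
    if np.any(v < 0):
        raise ValidationError("streamline density must be nonnegative")
    total = v.sum()
    if total == 0:
        logger.warning("all-zero streamline density; empty mask")
        return np.array([], dtype=int)
    return np.flatnonzero(v > fraction * total)
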