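"""NIfTI volume/mask I/O, grid alignment checks, mask editing, and
centerline-range cropping.

The in-memory containers are deliberately thin: an :class:`ImageGrid` is a
3-D array of Hounsfield units plus millimetre voxel spacing and a world
origin; a :class:`BinaryMask` is a boolean field on the same lattice.
Voxel indexing is 0-based and the world coordinate of voxel ``(i, j, k)``
is ``origin + (i, j, k) * spacing`` per axis.  Oblique acquisitions are
rejected on load: every distance computation downstream assumes an
axis-aligned grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

__all__ = [
    "ImageGrid",
    "BinaryMask",
    "AnalysisRange",
    "AlignmentVerdict",
    "load_volume",
    "load_mask",
    "save_volume",
    "save_mask",
    "check_aligned",
    "exclude_region",
    "centerline_arc_length",
    "crop_range",
]

#: Spacing/shape agreement tolerance for alignment checks, in mm.
SPACING_TOL_MM = 1e-4

#: Maximum off-diagonal affine component (relative to spacing) tolerated
#: before an acquisition is considered oblique and rejected.
OBLIQUITY_TOL = 1e-3


@dataclass
class ImageGrid:
    """3-D scalar HU field with physical geometry.

    Attributes
    ----------
    values : np.ndarray
        HU per voxel, float, shape (nx, ny, nz).  Stored as float even for
        integer-typed files so ring means are not quantised.
    spacing : tuple of float
        mm per voxel along each axis; all positive.
    origin : tuple of float
        World coordinate (mm) of voxel (0, 0, 0).
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(
                f"ImageGrid requires a 3-D lattice, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("HU values must be finite")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape


@dataclass
class BinaryMask:
    """Boolean field on an :class:`ImageGrid` lattice."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3 or min(self.values.shape) < 1:
            raise ValueError(
                f"BinaryMask requires a 3-D lattice, got shape {self.values.shape}"
            )
        self.spacing = tuple(float(s) for s in self.spacing)
        self.origin = tuple(float(o) for o in self.origin)
        if len(self.spacing) != 3 or any(s <= 0 for s in self.spacing):
            raise ValueError(f"spacing must be 3 positive reals, got {self.spacing}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def count(self) -> int:
        return int(self.values.sum())


@dataclass(frozen=True)
class AnalysisRange:
    """Arc-length bounds (mm) along the vessel centerline delimiting the
    quantitative analysis segment."""

    lo_mm: float
    hi_mm: float

    def __post_init__(self) -> None:
        if not (0 <= self.lo_mm < self.hi_mm):
            raise ValueError(
                f"require 0 <= lo_mm < hi_mm, got ({self.lo_mm}, {self.hi_mm})"
            )


@dataclass
class AlignmentVerdict:
    ok: bool
    mismatches: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.ok


def _affine_geometry(img: nib.Nifti1Image) -> tuple[tuple, tuple]:
    """Extract (spacing, origin) from an axis-aligned NIfTI affine.

    Rejects non-positive spacing and oblique rotations.
    """
    aff = np.asarray(img.affine, dtype=float)
    rot = aff[:3, :3]
    spacing = np.sqrt((rot**2).sum(axis=0))
    if np.any(spacing <= 0) or not np.all(np.isfinite(spacing)):
        raise ValueError(
            f"non-positive voxel spacing in NIfTI header (pixdim/affine): {spacing}"
        )
    # off-diagonal components, relative to the column norm, must vanish
    off = np.abs(rot) - np.diag(np.abs(np.diag(rot)))
    if np.any(off / spacing[np.newaxis, :] > OBLIQUITY_TOL):
        raise ValueError(
            "oblique NIfTI affine (non-axis-aligned rotation); "
            "resample to an axis-aligned grid first"
        )
    origin = aff[:3, 3]
    return tuple(spacing.tolist()), tuple(origin.tolist())


def _load_array(path: str | Path) -> tuple[np.ndarray, tuple, tuple]:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    # tolerate 4-D files with a singleton trailing axis (common exporter quirk)
    if data.ndim == 4 and data.shape[3] == 1:
        data = data[..., 0]
    if data.ndim != 3:
        raise ValueError(
            f"{path.name}: expected a 3-D payload (dim field), got shape {data.shape}"
        )
    spacing, origin = _affine_geometry(img)
    return data, spacing, origin


def load_volume(path: str | Path) -> ImageGrid:
    """Read a 3-D NIfTI CT volume; values are interpreted as HU."""
    data, spacing, origin = _load_array(path)
    return ImageGrid(values=data.astype(np.float64), spacing=spacing, origin=origin)


def load_mask(path: str | Path) -> BinaryMask:
    """Read a 3-D NIfTI label image; any non-zero voxel is foreground."""
    data, spacing, origin = _load_array(path)
    return BinaryMask(values=data != 0, spacing=spacing, origin=origin)


def _affine_of(spacing, origin) -> np.ndarray:
    aff = np.eye(4)
    aff[:3, :3] = np.diag(spacing)
    aff[:3, 3] = origin
    return aff


def save_volume(grid: ImageGrid, path: str | Path) -> None:
    img = nib.Nifti1Image(grid.values.astype(np.float64), _affine_of(grid.spacing, grid.origin))
    nib.save(img, str(path))


def save_mask(mask: BinaryMask, path: str | Path) -> None:
    img = nib.Nifti1Image(
        mask.values.astype(np.uint8), _affine_of(mask.spacing, mask.origin)
    )
    nib.save(img, str(path))


def check_aligned(grid: ImageGrid | BinaryMask, mask: ImageGrid | BinaryMask) -> AlignmentVerdict:
    """Verify two fields live on the same lattice.

    Shapes must match exactly and spacings within ``SPACING_TOL_MM``; the
    verdict lists every mismatching axis (1-based in messages).
    """
    mismatches: list[str] = []
    for ax in range(3):
        if grid.shape[ax] != mask.shape[ax]:
            mismatches.append(
                f"axis {ax + 1}: shape {grid.shape[ax]} != {mask.shape[ax]}"
            )
        if abs(grid.spacing[ax] - mask.spacing[ax]) > SPACING_TOL_MM:
            mismatches.append(
                f"axis {ax + 1}: spacing {grid.spacing[ax]} != {mask.spacing[ax]} mm"
            )
    return AlignmentVerdict(ok=not mismatches, mismatches=mismatches)


def require_aligned(grid, mask) -> None:
    v = check_aligned(grid, mask)
    if not v:
        raise ValueError("grid/mask misaligned: " + "; ".join(v.mismatches))


def exclude_region(
    mask: BinaryMask, box: tuple[tuple[int, int], tuple[int, int], tuple[int, int]]
) -> BinaryMask:
    """Clear all voxels inside a half-open voxel-index box ``(lo, hi)`` per axis.

    Used for manual artifact exclusion (e.g. metal around stent grafts).
    The input mask is left unmodified.  A box lying entirely outside the
    lattice on any axis raises, to catch coordinate mistakes; boxes partially
    outside are clamped; an empty box (lo == hi) is a no-op.
    """
    out = mask.values.copy()
    slicer = []
    for ax, (lo, hi) in enumerate(box):
        n = mask.shape[ax]
        if lo > hi:
            raise ValueError(f"axis {ax}: box lo {lo} > hi {hi}")
        if hi <= 0 or lo >= n:
            if lo != hi:
                raise ValueError(
                    f"axis {ax}: box [{lo}, {hi}) entirely outside lattice of size {n}"
                )
        slicer.append(slice(max(lo, 0), min(hi, n)))
    out[tuple(slicer)] = False
    return BinaryMask(values=out, spacing=mask.spacing, origin=mask.origin)


def centerline_arc_length(
    mask: BinaryMask, slice_axis: int = 2
) -> tuple[np.ndarray, np.ndarray]:
    """Per-slice centroid centerline and its cumulative arc-length.

    The centerline is the polyline of mask-voxel centroids of successive
    slices along ``slice_axis`` (in world mm); slices without mask voxels
    carry no centerline point.  This is a deliberate stand-in for dedicated
    centerline-extraction software and is adequate for near-tubular masks.

    Returns
    -------
    slice_indices : int array
        Indices of slices containing mask voxels, in order.
    arc_mm : float array
        Cumulative Euclidean arc-length (mm) along the centroid polyline;
        the first mask-bearing slice sits at 0.
    """
    if mask.count() == 0:
        raise ValueError("empty mask: no centerline")
    vox = np.argwhere(mask.values)
    spacing = np.asarray(mask.spacing)
    origin = np.asarray(mask.origin)
    ks = np.unique(vox[:, slice_axis])
    pts = np.empty((len(ks), 3))
    for row, k in enumerate(ks):
        sel = vox[vox[:, slice_axis] == k]
        pts[row] = origin + sel.mean(axis=0) * spacing
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg)])
    return ks, arc


def crop_range(
    grid: ImageGrid,
    mask: BinaryMask,
    range_mm: AnalysisRange,
    slice_axis: int = 2,
) -> tuple[ImageGrid, BinaryMask]:
    """Keep only the slices whose centerline arc-length lies inside the
    analysis range.

    Grid and mask are cropped identically; slices without mask voxels have
    no arc-length coordinate and are dropped.
    """
    require_aligned(grid, mask)
    ks, arc = centerline_arc_length(mask, slice_axis=slice_axis)
    keep = ks[(arc >= range_mm.lo_mm) & (arc <= range_mm.hi_mm)]
    if keep.size == 0:
        raise ValueError(
            f"analysis range [{range_mm.lo_mm}, {range_mm.hi_mm}] mm selects no slice "
            f"(centerline spans 0..{arc[-1]:.3f} mm)"
        )
    new_origin = list(grid.origin)
    new_origin[slice_axis] += int(keep[0]) * grid.spacing[slice_axis]
    g = ImageGrid(
        values=np.take(grid.values, keep, axis=slice_axis),
        spacing=grid.spacing,
        origin=tuple(new_origin),
    )
    m = BinaryMask(
        values=np.take(mask.values, keep, axis=slice_axis),
        spacing=mask.spacing,
        origin=tuple(new_origin),
    )
    return g, m
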