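"""Synthetic CT phantoms with ground-truth perivascular fat structure.

A phantom emulates a contrast-filled aorta: a tube (straight or helical
along the slice axis) of bright lumen (~ +300 HU) wrapped in a vessel wall
(~ +40 HU), surrounded by two adipose shells whose mean HU is configurable
within the fat window, embedded in soft tissue (~ +20 HU).  The shells are
painted by the same voxel-center Euclidean-distance bands the quantification
pipeline uses for its rings, so on a noiseless phantom the recovered ring
statistics equal the configured shell statistics exactly — the phantom is a
ground-truth oracle, not merely a plausible image.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from .pvat_quant import FatWindow, surface_distance_map
from .volume_io import BinaryMask, ImageGrid

__all__ = ["PhantomSpec", "make_phantom"]


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and attenuation of a synthetic perivascular-fat phantom.

    Lattice and spacing default to a clinically plausible reconstruction
    (sub-millimetre in-plane, 0.625 mm slices).  ``centerline`` is
    ``"straight"`` or ``"helical"``; a helical tube exercises arc-length
    logic where centerline length exceeds the z-extent.
    """

    shape: tuple[int, int, int] = (80, 80, 40)
    spacing: tuple[float, float, float] = (0.7, 0.7, 0.625)
    centerline: str = "straight"
    helix_radius_mm: float = 4.0
    helix_pitch_mm: float = 20.0
    lumen_radius_mm: float = 8.0
    wall_thickness_mm: float = 2.0
    hu_lumen: float = 300.0
    hu_wall: float = 40.0
    hu_soft: float = 20.0
    hu_fat_close: float = -70.0
    hu_fat_distant: float = -80.0
    close_shell_mm: tuple[float, float] = (2.0, 5.0)
    distant_shell_mm: tuple[float, float] = (10.0, 12.0)
    noise_sd_hu: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.lumen_radius_mm <= 0:
            raise ValueError("lumen radius must be positive")
        if self.wall_thickness_mm < 0:
            raise ValueError("wall thickness must be non-negative")
        if self.centerline not in ("straight", "helical"):
            raise ValueError(f"unknown centerline kind {self.centerline!r}")
        w = FatWindow()
        for hu in (self.hu_fat_close, self.hu_fat_distant):
            if not (w.lo_hu <= hu <= w.hi_hu):
                raise ValueError(
                    f"fat shell HU {hu} outside the fat window "
                    f"[{w.lo_hu}, {w.hi_hu}]"
                )
        if self.noise_sd_hu < 0:
            raise ValueError("noise SD must be non-negative")


def _centerline_xy(spec: PhantomSpec) -> np.ndarray:
    """Per-slice (x, y) centerline position in world mm."""
    nz = spec.shape[2]
    cx = (spec.shape[0] - 1) / 2 * spec.spacing[0]
    cy = (spec.shape[1] - 1) / 2 * spec.spacing[1]
    z = np.arange(nz) * spec.spacing[2]
    if spec.centerline == "straight":
        return np.column_stack([np.full(nz, cx), np.full(nz, cy)])
    theta = 2 * np.pi * z / spec.helix_pitch_mm
    return np.column_stack(
        [cx + spec.helix_radius_mm * np.cos(theta),
         cy + spec.helix_radius_mm * np.sin(theta)]
    )


def make_phantom(spec: PhantomSpec) -> tuple[ImageGrid, BinaryMask, dict]:
    """Build the HU volume, the aortic mask (lumen + wall), and ground truth.

    Ground truth records per-shell voxel counts, the configured shell means,
    and the realised (post-noise) shell means.  Deterministic given
    ``spec.seed``.

    Raises if the distal shell would touch the lateral lattice bounds —
    a truncated shell would silently bias the recovered means.
    """
    sx, sy, sz = spec.spacing
    nx, ny, nz = spec.shape
    r_outer = spec.lumen_radius_mm + spec.wall_thickness_mm
    reach = r_outer + spec.distant_shell_mm[1]
    if spec.centerline == "helical":
        reach += spec.helix_radius_mm
    half_extent = min((nx - 1) / 2 * sx, (ny - 1) / 2 * sy)
    if reach >= half_extent:
        raise ValueError(
            f"distal fat shell (reach {reach:.1f} mm) exceeds the lateral "
            f"lattice half-extent ({half_extent:.1f} mm); enlarge the lattice"
        )

    cl = _centerline_xy(spec)
    x = np.arange(nx) * sx
    y = np.arange(ny) * sy
    # in-plane radial distance of every voxel center from the slice's centerline
    r = np.empty(spec.shape)
    for k in range(nz):
        r[:, :, k] = np.hypot(x[:, None] - cl[k, 0], y[None, :] - cl[k, 1])

    lumen = r <= spec.lumen_radius_mm
    mask_arr = r <= r_outer
    wall = mask_arr & ~lumen
    mask = BinaryMask(values=mask_arr, spacing=spec.spacing)

    dist = surface_distance_map(mask)
    close = (dist >= spec.close_shell_mm[0]) & (dist <= spec.close_shell_mm[1])
    distant = (dist >= spec.distant_shell_mm[0]) & (dist <= spec.distant_shell_mm[1])

    hu = np.full(spec.shape, spec.hu_soft, dtype=np.float64)
    hu[lumen] = spec.hu_lumen
    hu[wall] = spec.hu_wall
    hu[close] = spec.hu_fat_close
    hu[distant] = spec.hu_fat_distant

    rng = np.random.default_rng(spec.seed)
    if spec.noise_sd_hu > 0:
        hu = hu + rng.normal(0.0, spec.noise_sd_hu, size=spec.shape)

    grid = ImageGrid(values=hu, spacing=spec.spacing)
    truth = {
        "n_close": int(close.sum()),
        "n_distant": int(distant.sum()),
        "configured_hu_close": spec.hu_fat_close,
        "configured_hu_distant": spec.hu_fat_distant,
        "realized_hu_close": float(hu[close].mean()),
        "realized_hu_distant": float(hu[distant].mean()),
        "spec": asdict(spec),
    }
    return grid, mask, truth
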