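"""Voxel grids over the Talairach bounding box.

A :class:`GridSpec` declares an isotropic voxel lattice by the mm coordinate
of the first voxel center (``origin``), the spacing, and the shape.  Voxel
axes follow the Talairach convention: x left(-)/right(+), y posterior(-)/
anterior(+), z inferior(-)/superior(+), i.e. RAS+.

The default bounding box, x in [-90, 90], y in [-126, 90], z in [-72, 108] mm,
is a generous superset of the atlas brain: extra voxels are empty and leave
all probabilities unchanged.  The 2-mm grid places voxel centers on even mm
coordinates; the 1-mm grid is defined as its *child* grid (origin shifted by
half a child voxel, shape doubled) so that every 2-mm voxel is the exact
union of eight 1-mm voxels and factor-two resampling is volume-exact.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_BOUNDS: tuple[tuple[float, float], ...] = ((-90.0, 90.0), (-126.0, 90.0), (-72.0, 108.0))


def _round_half_away(u: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (per-axis rule)."""
    u = np.asarray(u, dtype=float)
    return np.trunc(u + np.copysign(0.5, u)).astype(np.int64)


@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel lattice in mm stereotaxic coordinates."""

    spacing: float
    origin: tuple[float, float, float]
    shape: tuple[int, int, int]

    def __post_init__(self) -> None:
        if self.spacing <= 0:
            raise ValueError("spacing must be positive")
        if any(int(n) <= 0 for n in self.shape):
            raise ValueError("shape must be positive")
        object.__setattr__(self, "origin", tuple(float(v) for v in self.origin))
        object.__setattr__(self, "shape", tuple(int(n) for n in self.shape))

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    @property
    def voxel_volume_mm3(self) -> float:
        return float(self.spacing) ** 3

    @property
    def affine(self) -> np.ndarray:
        """4x4 voxel-index -> mm affine (NIfTI convention, RAS+)."""
        aff = np.eye(4)
        aff[0, 0] = aff[1, 1] = aff[2, 2] = self.spacing
        aff[:3, 3] = self.origin
        return aff

    def voxel_to_coord(self, index: np.ndarray) -> np.ndarray:
        """mm coordinate(s) of voxel center(s); accepts (3,) or (n, 3)."""
        return np.asarray(self.origin) + np.asarray(index, dtype=float) * self.spacing

    def coord_to_voxel(self, coords: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Map mm coordinates to nearest voxel indices.

        Returns ``(indices, in_grid)`` where ``indices`` is (n, 3) int and
        ``in_grid`` a boolean mask; out-of-grid coordinates keep their raw
        (possibly out-of-range) rounded index but are flagged False.
        """
        coords = np.atleast_2d(np.asarray(coords, dtype=float))
        idx = _round_half_away((coords - np.asarray(self.origin)) / self.spacing)
        in_grid = np.all((idx >= 0) & (idx < np.asarray(self.shape)), axis=1)
        return idx, in_grid

    def contains_coord(self, coord) -> bool:
        _, ok = self.coord_to_voxel(coord)
        return bool(ok[0])

    def axis_coords(self, axis: int) -> np.ndarray:
        """Voxel-center mm coordinates along one axis."""
        return self.origin[axis] + self.spacing * np.arange(self.shape[axis])

    def child(self) -> "GridSpec":
        """Grid at half the spacing whose voxels exactly tile this grid."""
        half = self.spacing / 2.0
        origin = tuple(o - half / 2.0 for o in self.origin)
        return GridSpec(half, origin, tuple(2 * n for n in self.shape))

    def parent(self) -> "GridSpec":
        """Grid at double the spacing of which this grid is the child tiling."""
        if any(n % 2 for n in self.shape):
            raise ValueError("parent grid requires an even shape on every axis")
        origin = tuple(o + self.spacing / 2.0 for o in self.origin)
        return GridSpec(self.spacing * 2.0, origin, tuple(n // 2 for n in self.shape))

    def close_to(self, other: "GridSpec", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.spacing - other.spacing) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


def make_grid(spacing: float = 2.0, bounds=DEFAULT_BOUNDS) -> GridSpec:
    """Standard analysis grid covering a Talairach bounding box.

    ``spacing`` must be 1 or 2 mm.  The 2-mm grid anchors voxel centers at
    the lower bounds; the 1-mm grid is its child tiling.
    """
    lows = [float(lo) for lo, _ in bounds]
    shape = [int(np.floor((hi - lo) / 2.0)) + 1 for lo, hi in bounds]
    base = GridSpec(2.0, tuple(lows), tuple(shape))
    if spacing == 2.0 or spacing == 2:
        return base
    if spacing == 1.0 or spacing == 1:
        return base.child()
    raise ValueError("supported grid spacings are 1 and 2 mm")


def grid_from_affine(affine: np.ndarray, shape) -> GridSpec:
    """Derive a GridSpec from a NIfTI affine (must be axis-aligned RAS+ isotropic)."""
    affine = np.asarray(affine, dtype=float)
    diag = np.diag(affine)[:3]
    off_diag = affine[:3, :3] - np.diag(diag)
    if not np.allclose(off_diag, 0.0, atol=1e-6):
        raise ValueError("only axis-aligned (diagonal) affines are supported")
    if np.any(diag <= 0):
        raise ValueError("affine must be RAS+ with positive voxel sizes")
    if not np.allclose(diag, diag[0], atol=1e-6):
        raise ValueError("only isotropic grids are supported")
    return GridSpec(float(diag[0]), tuple(affine[:3, 3]), tuple(shape[:3]))
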