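"""Region-of-interest construction and manipulation on voxel grids.

ROIs are binary masks on a declared :class:`~brainbehavior.grid.GridSpec`.
They can be built the ways regional behavioral analyses typically need:
thresholding a statistical parametric map (closed threshold, value >= t),
selecting labels from an integer atlas, placing spheres at mm coordinates,
morphological dilation with the full 3x3x3 structuring element, half-space
clipping (e.g. isolating the posterior part of a gyrus at a y cutoff), and
exact factor-two precision conversion between 1-mm and 2-mm grids.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
from scipy import ndimage

from .grid import GridSpec, grid_from_affine

logger = logging.getLogger(__name__)

_AXES = {"x": 0, "y": 1, "z": 2, 0: 0, 1: 1, 2: 2}


@dataclass
class ROIMask:
    """Binary voxel mask on a declared grid."""

    grid: GridSpec
    data: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        data = np.asarray(self.data)
        if data.shape != self.grid.shape:
            raise ValueError(f"mask shape {data.shape} does not match grid {self.grid.shape}")
        self.data = data.astype(bool)

    @property
    def n_voxels(self) -> int:
        return int(self.data.sum())

    @property
    def volume_mm3(self) -> float:
        return self.n_voxels * self.grid.voxel_volume_mm3

    def copy(self) -> "ROIMask":
        return ROIMask(self.grid, self.data.copy(), self.provenance)

    def intersect(self, other: "ROIMask") -> "ROIMask":
        if not self.grid.close_to(other.grid):
            raise ValueError("cannot intersect masks on different grids")
        return ROIMask(self.grid, self.data & other.data,
                       provenance=f"({self.provenance}) & ({other.provenance})")


def roi_from_statmap(statmap: np.ndarray, grid: GridSpec, threshold: float) -> ROIMask:
    """Threshold a voxelwise statistical map: voxel set iff value >= threshold.

    Non-finite voxels are treated as below threshold (and logged).
    """
    statmap = np.asarray(statmap, dtype=float)
    if statmap.shape != grid.shape:
        raise ValueError("statistical map shape does not match grid")
    finite = np.isfinite(statmap)
    n_bad = int((~finite).sum())
    if n_bad:
        logger.warning("statmap has %d non-finite voxels; treated as sub-threshold", n_bad)
    data = finite & (statmap >= threshold)
    return ROIMask(grid, data, provenance=f"statmap >= {threshold}")


def roi_from_labels(atlas: np.ndarray, grid: GridSpec, values) -> ROIMask:
    """Select the voxels of an integer label atlas whose label is in ``values``."""
    atlas = np.asarray(atlas)
    if not np.issubdtype(atlas.dtype, np.integer):
        if not np.allclose(atlas, np.rint(atlas)):
            raise ValueError("atlas image is not integer-valued")
        atlas = np.rint(atlas).astype(np.int64)
    if atlas.shape != grid.shape:
        raise ValueError("atlas shape does not match grid")
    values = sorted(int(v) for v in values)
    data = np.isin(atlas, values)
    mask = ROIMask(grid, data, provenance=f"atlas labels {values}")
    if mask.n_voxels == 0:
        logger.warning("label selection %s produced an empty ROI", values)
    return mask


def roi_sphere(center, radius: float, grid: GridSpec) -> ROIMask:
    """Sphere ROI: voxel set iff its center lies within ``radius`` mm of ``center``."""
    if radius <= 0:
        raise ValueError("sphere radius must be positive")
    center = np.asarray(center, dtype=float)
    dist2 = np.zeros(grid.shape)
    for ax in range(3):
        d = grid.axis_coords(ax) - center[ax]
        shape = [1, 1, 1]
        shape[ax] = -1
        dist2 = dist2 + (d ** 2).reshape(shape)
    data = dist2 <= radius ** 2
    return ROIMask(grid, data, provenance=f"sphere r={radius}mm @ {tuple(center)}")


_STRUCT_3X3X3 = np.ones((3, 3, 3), dtype=bool)


def dilate(mask: ROIMask, iterations: int = 1) -> ROIMask:
    """Morphological dilation with the full 3x3x3 kernel, applied iteratively."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0 or mask.n_voxels == 0:
        out = mask.copy()
        out.provenance = f"{mask.provenance} | dilate x{iterations}"
        return out
    data = ndimage.binary_dilation(mask.data, structure=_STRUCT_3X3X3, iterations=iterations)
    return ROIMask(mask.grid, data, provenance=f"{mask.provenance} | dilate x{iterations}")


def clip_halfspace(mask: ROIMask, axis, cutoff_mm: float, keep: str = "negative") -> ROIMask:
    """Keep only voxels on one side of an axis-aligned plane.

    ``keep='negative'`` keeps voxel centers with coordinate <= cutoff (e.g.
    posterior of a y cutoff); ``keep='positive'`` keeps coordinate >= cutoff.
    The cutoff plane itself is kept on either side.
    """
    ax = _AXES[axis]
    coords = mask.grid.axis_coords(ax)
    if keep == "negative":
        sel = coords <= cutoff_mm
    elif keep == "positive":
        sel = coords >= cutoff_mm
    else:
        raise ValueError("keep must be 'negative' or 'positive'")
    shape = [1, 1, 1]
    shape[ax] = -1
    data = mask.data & sel.reshape(shape)
    return ROIMask(mask.grid, data,
                   provenance=f"{mask.provenance} | clip {axis} {keep} of {cutoff_mm}mm")


def resample_mask(mask: ROIMask, target_spacing: float, rule: str = "majority") -> ROIMask:
    """Convert a mask between 1-mm and 2-mm precision.

    Up-conversion (2 -> 1 mm) replaces each voxel by its eight children and
    preserves volume exactly.  Down-conversion (1 -> 2 mm) sets a parent
    voxel iff at least half of its eight children are set (``rule='majority'``,
    ties set) or iff any child is set (``rule='any'``).
    """
    if float(mask.grid.spacing) not in (1.0, 2.0) or float(target_spacing) not in (1.0, 2.0):
        raise ValueError("supported spacings for precision conversion are 1 and 2 mm")
    spacing = float(mask.grid.spacing)
    target = float(target_spacing)
    if spacing == target:
        return mask.copy()
    if target < spacing:  # 2 -> 1 mm
        data = mask.data
        for ax in range(3):
            data = np.repeat(data, 2, axis=ax)
        return ROIMask(mask.grid.child(), data, provenance=f"{mask.provenance} | up to 1mm")
    # 1 -> 2 mm: pad to an even shape (zeros at the high end), then pool blocks
    data = mask.data
    pad = [(0, n % 2) for n in data.shape]
    grid = mask.grid
    if any(p for _, p in pad):
        data = np.pad(data, pad)
        grid = GridSpec(grid.spacing, grid.origin, data.shape)
    nx, ny, nz = (n // 2 for n in data.shape)
    blocks = data.reshape(nx, 2, ny, 2, nz, 2)
    child_count = blocks.sum(axis=(1, 3, 5))
    if rule == "majority":
        out = child_count >= 4
    elif rule == "any":
        out = child_count >= 1
    else:
        raise ValueError("rule must be 'majority' or 'any'")
    return ROIMask(grid.parent(), out, provenance=f"{mask.provenance} | down to 2mm ({rule})")


def mask_volume(mask: ROIMask) -> float:
    """Mask volume in mm^3 (#set voxels times voxel volume)."""
    return mask.volume_mm3


# ---------------------------------------------------------------------------
# NIfTI I/O

def save_mask(mask: ROIMask, path: str | Path) -> None:
    img = nib.Nifti1Image(mask.data.astype(np.uint8), mask.grid.affine)
    img.header.set_xyzt_units("mm")
    if mask.provenance:
        img.header["descrip"] = mask.provenance.encode()[:79]
    nib.save(img, str(path))


def load_mask(path: str | Path) -> ROIMask:
    img = nib.load(str(path))
    grid = grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj) > 0
    return ROIMask(grid, data, provenance=str(path))


def load_statmap(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Load a scalar NIfTI volume, returning (data, grid)."""
    img = nib.load(str(path))
    grid = grid_from_affine(img.affine, img.shape)
    return np.asanyarray(img.dataobj).astype(float), grid


def load_labels(path: str | Path) -> tuple[np.ndarray, GridSpec]:
    """Load an integer label NIfTI volume, returning (labels, grid)."""
    img = nib.load(str(path))
    grid = grid_from_affine(img.affine, img.shape)
    data = np.asanyarray(img.dataobj)
    return np.rint(data).astype(np.int64), grid
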