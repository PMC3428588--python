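"""Affine coordinate transforms between stereotaxic spaces.

All internal analysis is carried out in Talairach coordinates.  Data fitted
to the MNI template are adjusted with an affine MNI->Talairach transform;
the package ships the pooled icbm2tal coefficient matrices (one fitted to
SPM-normalized brains, one to FSL-normalized brains) and accepts any
user-supplied 4x4 matrix as a whitespace-delimited text file.

Masks are resampled by nearest-neighbor *pull* mapping: each output voxel
center is mapped through the inverse transform and takes the value of the
input voxel it lands in, which keeps binary masks binary and leaves no holes.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .grid import GridSpec

#: Pooled ICBM-152 -> Talairach affine fitted on SPM-normalized brains.
ICBM_SPM_TO_TAL = np.array(
    [
        [0.9254, 0.0024, -0.0118, -1.0207],
        [-0.0048, 0.9316, -0.0871, -1.7667],
        [0.0152, 0.0883, 0.8924, 4.0926],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

#: Pooled ICBM-152 -> Talairach affine fitted on FSL-normalized brains.
ICBM_FSL_TO_TAL = np.array(
    [
        [0.9464, 0.0034, -0.0026, -1.0680],
        [-0.0083, 0.9479, -0.0580, -1.0239],
        [0.0053, 0.0617, 0.9010, 3.1883],
        [0.0, 0.0, 0.0, 1.0],
    ]
)

MNI_TO_TAL_VARIANTS = {"spm": ICBM_SPM_TO_TAL, "fsl": ICBM_FSL_TO_TAL}


@dataclass(frozen=True)
class AffineTransform:
    """Homogeneous 4x4 mm->mm coordinate transform."""

    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (4, 4):
            raise ValueError("transform matrix must be 4x4")
        if not np.allclose(m[3], [0.0, 0.0, 0.0, 1.0]):
            raise ValueError("last row of an affine transform must be (0,0,0,1)")
        if abs(np.linalg.det(m[:3, :3])) < 1e-12:
            raise ValueError("transform is singular")
        m = m.copy()
        m.setflags(write=False)
        object.__setattr__(self, "matrix", m)

    @classmethod
    def identity(cls) -> "AffineTransform":
        return cls(np.eye(4))

    @classmethod
    def mni_to_tal(cls, variant: str = "spm") -> "AffineTransform":
        try:
            return cls(MNI_TO_TAL_VARIANTS[variant])
        except KeyError:
            raise ValueError(
                f"unknown MNI->TAL variant {variant!r}; choose from {sorted(MNI_TO_TAL_VARIANTS)}"
            ) from None

    @classmethod
    def from_file(cls, path: str | Path) -> "AffineTransform":
        """Load a 4x4 whitespace-delimited matrix from a text file."""
        m = np.loadtxt(path)
        return cls(m)

    def inverse(self) -> "AffineTransform":
        return AffineTransform(np.linalg.inv(self.matrix))

    def apply_to_coord(self, coord) -> tuple[float, float, float]:
        """Transform a single (x, y, z) mm coordinate."""
        out = self.apply_to_coords(np.asarray(coord, dtype=float)[None, :])[0]
        return (float(out[0]), float(out[1]), float(out[2]))

    def apply_to_coords(self, coords: np.ndarray) -> np.ndarray:
        """Transform an (n, 3) array of mm coordinates."""
        coords = np.asarray(coords, dtype=float)
        return coords @ self.matrix[:3, :3].T + self.matrix[:3, 3]


def apply_to_mask(t: AffineTransform, mask, out_grid: GridSpec):
    """Resample a binary mask through an affine onto ``out_grid``.

    Nearest-neighbor pull resampling: an output voxel is set iff its center,
    mapped through the inverse transform, falls inside a set input voxel.
    """
    from .roi import ROIMask  # local import to avoid a cycle

    inv = t.inverse()
    idx = np.indices(out_grid.shape).reshape(3, -1).T
    centers = out_grid.voxel_to_coord(idx)
    src_mm = inv.apply_to_coords(centers)
    src_idx, in_grid = mask.grid.coord_to_voxel(src_mm)
    out = np.zeros(out_grid.n_voxels, dtype=bool)
    if in_grid.any():
        flat = np.ravel_multi_index(src_idx[in_grid].T, mask.grid.shape)
        out[in_grid] = mask.data.ravel()[flat]
    return ROIMask(out_grid, out.reshape(out_grid.shape),
                   provenance=f"{mask.provenance} | affine-resampled")
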