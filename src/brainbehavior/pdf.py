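"""Build 4-D behavioral probability-density images from foci tables.

The pipeline: foci for each behavioral sub-domain are binned onto an
isotropic Talairach grid (adding one count at the voxel nearest each
coordinate), each 3-D count image is divided by its whole-brain focus total
N_b to give a probability-density image summing to one, and the 51 channels
are concatenated — in taxonomy order — into a single 4-D image PDF(x, y, z, b)
serialized as gzip-compressed NIfTI-1 with a JSON sidecar recording channel
order and N_b.

Internally the object keeps the integer tallies and derives PDF channels by
division on access: probabilities such as a whole-brain ROI sum then reduce
to exact integer ratios (N_b/N_b == 1.0 bit-exactly) instead of rounded
floating sums.
"""

from __future__ import annotations

import json
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np

from .foci import FociTable
from .grid import GridSpec, grid_from_affine
from .taxonomy import BehaviorTaxonomy, load_taxonomy

logger = logging.getLogger(__name__)


@dataclass
class FociCountImage:
    """3-D tally of activation foci for one behavioral sub-domain."""

    grid: GridSpec
    counts: np.ndarray
    subdomain_id: int | None = None
    n_dropped: int = 0  # foci outside the grid bounding box

    @property
    def n_foci(self) -> int:
        """In-grid focus total N_b."""
        return int(self.counts.sum())


def build_count_image(coords, grid: GridSpec, subdomain_id: int | None = None) -> FociCountImage:
    """Bin mm coordinates onto the grid, one count per focus at the nearest voxel.

    Out-of-grid foci are dropped, tallied, and reported via a warning log.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    counts = np.zeros(grid.shape, dtype=np.int32)
    if len(coords) == 0:
        return FociCountImage(grid, counts, subdomain_id, 0)
    idx, in_grid = grid.coord_to_voxel(coords)
    dropped = int((~in_grid).sum())
    if dropped:
        logger.warning(
            "sub-domain %s: %d of %d foci fall outside the grid and were dropped",
            subdomain_id, dropped, len(coords),
        )
    kept = idx[in_grid]
    if len(kept):
        flat = np.ravel_multi_index(kept.T, grid.shape)
        np.add.at(counts.ravel(), flat, 1)
    return FociCountImage(grid, counts, subdomain_id, dropped)


def normalize_to_pdf(img: FociCountImage) -> tuple[np.ndarray, int]:
    """Convert a count image to a probability density channel and its N_b.

    A zero-focus image yields an all-zero channel with N_b = 0 (warned, not
    an error): the sub-domain simply carries no evidence.
    """
    n_b = img.n_foci
    if n_b == 0:
        logger.warning("sub-domain %s has no in-grid foci; channel is all zero",
                       img.subdomain_id)
        return np.zeros(img.grid.shape, dtype=float), 0
    return img.counts / float(n_b), n_b


@dataclass
class BehaviorPDF4D:
    """4-D behavioral probability density: one channel per sub-domain.

    ``counts`` holds the per-channel integer foci tallies with shape
    ``grid.shape + (51,)``; the normalized channel PDF(x, y, z, b) is
    ``counts[..., b] / n_foci[b]``.
    """

    grid: GridSpec
    counts: np.ndarray
    n_foci: np.ndarray
    taxonomy: BehaviorTaxonomy = field(default_factory=load_taxonomy)
    n_dropped: np.ndarray | None = None

    def __post_init__(self) -> None:
        expected = self.grid.shape + (len(self.taxonomy),)
        if self.counts.shape != expected:
            raise ValueError(f"counts shape {self.counts.shape} != {expected}")
        self.n_foci = np.asarray(self.n_foci, dtype=np.int64)
        if self.n_dropped is None:
            self.n_dropped = np.zeros(len(self.taxonomy), dtype=np.int64)

    @property
    def n_channels(self) -> int:
        return self.counts.shape[3]

    def channel_index(self, subdomain_id: int) -> int:
        return self.taxonomy.channel_index(subdomain_id)

    def channel_counts(self, subdomain_id: int) -> np.ndarray:
        return self.counts[..., self.channel_index(subdomain_id)]

    def channel(self, subdomain_id: int) -> np.ndarray:
        """Normalized PDF channel for one sub-domain (zeros if N_b = 0)."""
        i = self.channel_index(subdomain_id)
        n = int(self.n_foci[i])
        if n == 0:
            return np.zeros(self.grid.shape, dtype=float)
        return self.counts[..., i] / float(n)

    def channel_sums(self) -> np.ndarray:
        """Voxel sum of each normalized channel (1.0 wherever N_b > 0)."""
        sums = np.zeros(self.n_channels)
        totals = self.counts.sum(axis=(0, 1, 2), dtype=np.int64)
        populated = self.n_foci > 0
        sums[populated] = totals[populated] / self.n_foci[populated].astype(float)
        return sums

    def pdf_array(self, dtype=np.float32) -> np.ndarray:
        """Dense normalized 4-D array (for serialization/visualisation)."""
        denom = np.where(self.n_foci > 0, self.n_foci, 1).astype(float)
        return (self.counts / denom).astype(dtype)


def assemble_pdf4d(
    foci: FociTable,
    grid: GridSpec,
    taxonomy: BehaviorTaxonomy | None = None,
) -> BehaviorPDF4D:
    """Build the 4-D PDF image from a foci table.

    Sub-domains absent from the table produce all-zero channels with
    N_b = 0; channel order follows taxonomy order.
    """
    taxonomy = taxonomy or foci.taxonomy
    n_ch = len(taxonomy)
    counts = np.zeros(grid.shape + (n_ch,), dtype=np.int32)
    n_foci = np.zeros(n_ch, dtype=np.int64)
    n_dropped = np.zeros(n_ch, dtype=np.int64)
    for i, sid in enumerate(taxonomy.ids()):
        img = build_count_image(foci.coords_for(sid), grid, sid)
        counts[..., i] = img.counts
        n_foci[i] = img.n_foci
        n_dropped[i] = img.n_dropped
    return BehaviorPDF4D(grid, counts, n_foci, taxonomy, n_dropped)


# ---------------------------------------------------------------------------
# Serialization: gzip-compressed NIfTI-1 + JSON sidecar

def _sidecar_path(path: str | Path) -> Path:
    path = str(path)
    stripped = re.sub(r"\.nii(\.gz)?$", "", path)
    return Path(stripped + ".json")


def write_pdf4d(pdf: BehaviorPDF4D, path: str | Path) -> None:
    """Write the normalized 4-D PDF as .nii.gz plus a JSON sidecar with N_b."""
    path = str(path)
    if not path.endswith(".nii.gz"):
        raise ValueError("4-D PDF images are written as gzip-compressed NIfTI (.nii.gz)")
    img = nib.Nifti1Image(pdf.pdf_array(np.float32), pdf.grid.affine)
    img.header.set_xyzt_units("mm")
    nib.save(img, path)
    sidecar = {
        "spacing": pdf.grid.spacing,
        "origin": list(pdf.grid.origin),
        "shape": list(pdf.grid.shape),
        "subdomain_ids": list(pdf.taxonomy.ids()),
        "n_foci": [int(n) for n in pdf.n_foci],
        "n_dropped": [int(n) for n in pdf.n_dropped],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))
    logger.info("wrote 4-D PDF (%d channels) to %s", pdf.n_channels, path)


def read_pdf4d(path: str | Path, taxonomy: BehaviorTaxonomy | None = None) -> BehaviorPDF4D:
    """Read a 4-D PDF written by :func:`write_pdf4d` (sidecar required)."""
    taxonomy = taxonomy or load_taxonomy()
    sidecar_path = _sidecar_path(path)
    if not sidecar_path.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar_path}: the per-channel focus totals N_b "
            "are required to interpret a 4-D PDF image"
        )
    meta = json.loads(sidecar_path.read_text())
    img = nib.load(str(path))
    if img.ndim != 4:
        raise ValueError(f"{path} is not a 4-D image")
    grid = grid_from_affine(img.affine, img.shape)
    declared = GridSpec(meta["spacing"], tuple(meta["origin"]), tuple(meta["shape"]))
    if not grid.close_to(declared, tol=1e-3):
        raise ValueError("sidecar grid metadata disagrees with the NIfTI affine")
    if list(meta["subdomain_ids"]) != list(taxonomy.ids()):
        raise ValueError("sidecar channel order does not match the taxonomy")
    n_foci = np.asarray(meta["n_foci"], dtype=np.int64)
    data = np.asanyarray(img.dataobj).astype(np.float64)
    if data.shape[3] != len(taxonomy):
        raise ValueError(f"expected {len(taxonomy)} channels, found {data.shape[3]}")
    # recover integer tallies; exact as long as counts are far below 2^52
    counts = np.rint(data * n_foci[None, None, None, :]).astype(np.int32)
    n_dropped = np.asarray(meta.get("n_dropped", np.zeros(len(taxonomy))), dtype=np.int64)
    return BehaviorPDF4D(grid, counts, n_foci, taxonomy, n_dropped)
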