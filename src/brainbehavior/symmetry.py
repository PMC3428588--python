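"""Left-right symmetry of activation foci.

Foci are tallied by hemisphere (Talairach convention: x < 0 is left), per
behavioral sub-domain or per supplied region mask, and the departure of the
left fraction f = n_left / (n_left + n_right) from 0.5 is scored with the
one-sample proportion statistic::

    z = (f - 0.5) / sqrt(f (1 - f) / N),   N = n_left + n_right

Midline foci (x == 0) are excluded from both hemispheres by default; the
``midline`` policy can instead assign them to either side.

``LATERALITY_COUNTS_2012`` ships the hemispheric tallies of the 13
sub-domains with statistically significant asymmetry in the 2012 BrainMap
snapshot (the classic leftward language dominance, plus one rightward case,
response inhibition); they serve as reference inputs for regression checks.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .foci import FociTable
from .roi import ROIMask
from .taxonomy import load_taxonomy

logger = logging.getLogger(__name__)

DEFAULT_SYMMETRY_Z_THRESHOLD = 3.0

#: (domain, sub-domain name) -> (n_left, n_right); 2012 BrainMap snapshot.
LATERALITY_COUNTS_2012: dict[tuple[str, str], tuple[int, int]] = {
    ("Action", "Execution:Other"): (3924, 3270),
    ("Action", "Execution:Speech"): (1625, 1254),
    ("Action", "Imagination"): (645, 454),
    ("Action", "Inhibition"): (1036, 1254),
    ("Cognition", "Language:Orthography"): (1050, 662),
    ("Cognition", "Language:Other"): (660, 415),
    ("Cognition", "Language:Phonology"): (907, 525),
    ("Cognition", "Language:Semantics"): (4232, 2349),
    ("Cognition", "Language:Speech"): (3829, 2523),
    ("Cognition", "Language:Syntax"): (392, 196),
    ("Cognition", "Memory:Explicit"): (3459, 2736),
    ("Cognition", "Memory:Working"): (3591, 3311),
    ("Perception", "Somesthesis:Other"): (1157, 1009),
}


@dataclass(frozen=True)
class SymmetryResult:
    """Hemispheric tally and lateralization score for one label."""

    label: str
    n_left: int
    n_right: int
    z: float
    significant: bool

    @property
    def n_total(self) -> int:
        return self.n_left + self.n_right

    @property
    def left_fraction(self) -> float:
        if self.n_total == 0:
            return float("nan")
        return self.n_left / self.n_total


def lr_counts(coords, region: ROIMask | None = None, midline: str = "drop"):
    """Tally foci left (x < 0) and right (x > 0) of the midline.

    Returns ``(n_left, n_right, n_midline)``.  ``midline`` chooses what to do
    with x == 0 foci: ``'drop'`` (excluded, reported in the third slot),
    ``'left'`` or ``'right'`` (folded into a hemisphere).  An optional region
    mask filters foci (by nearest voxel membership) before tallying.
    """
    coords = np.asarray(coords, dtype=float).reshape(-1, 3)
    if region is not None and len(coords):
        idx, in_grid = region.grid.coord_to_voxel(coords)
        keep = in_grid.copy()
        if in_grid.any():
            flat = np.ravel_multi_index(idx[in_grid].T, region.grid.shape)
            keep[in_grid] = region.data.ravel()[flat]
        coords = coords[keep]
    x = coords[:, 0] if len(coords) else np.empty(0)
    n_left = int((x < 0).sum())
    n_right = int((x > 0).sum())
    n_mid = int((x == 0).sum())
    if midline == "drop":
        return n_left, n_right, n_mid
    if midline == "left":
        return n_left + n_mid, n_right, 0
    if midline == "right":
        return n_left, n_right + n_mid, 0
    raise ValueError("midline must be 'drop', 'left' or 'right'")


def symmetry_z(n_left: int, n_right: int) -> float:
    """One-sample z-score for the left fraction against 0.5.

    Degenerate tallies: fewer than two lateralized foci give NaN; a fraction
    of exactly 0 or 1 gives signed infinity (with a warning) since the
    plug-in variance vanishes.
    """
    n = n_left + n_right
    if n < 2:
        return float("nan")
    f = n_left / n
    if f == 0.0 or f == 1.0:
        logger.warning("all %d foci on one side; lateralization z is unbounded", n)
        return math.copysign(float("inf"), f - 0.5)
    return (f - 0.5) / math.sqrt(f * (1.0 - f) / n)


def symmetry_table(
    foci: FociTable,
    regions: dict[str, ROIMask] | None = None,
    z_threshold: float = DEFAULT_SYMMETRY_Z_THRESHOLD,
    midline: str = "drop",
) -> list[SymmetryResult]:
    """Lateralization results per sub-domain, or per region mask if given.

    With ``regions`` a mapping of label -> mask, all foci are pooled and
    filtered by each mask; otherwise one row is produced for every taxonomy
    sub-domain.  Significance is flagged at |z| >= ``z_threshold``
    (3.0 by default; 2.0 is the conventional per-region threshold).
    """
    results: list[SymmetryResult] = []
    if regions is not None:
        all_coords = np.array([r.coord for r in foci.records], dtype=float).reshape(-1, 3)
        for label, mask in regions.items():
            nl, nr, _ = lr_counts(all_coords, region=mask, midline=midline)
            z = symmetry_z(nl, nr)
            results.append(SymmetryResult(label, nl, nr, z,
                                          bool(math.isfinite(z) and abs(z) >= z_threshold)))
        return results
    taxonomy = foci.taxonomy or load_taxonomy()
    for sub in taxonomy.subdomains:
        nl, nr, _ = lr_counts(foci.coords_for(sub.id), midline=midline)
        z = symmetry_z(nl, nr)
        results.append(SymmetryResult(sub.full_name, nl, nr, z,
                                      bool(math.isfinite(z) and abs(z) >= z_threshold)))
    return results


def symmetry_frame(results: list[SymmetryResult]) -> pd.DataFrame:
    """Tabulate symmetry results (counts, left fraction, z, significance)."""
    return pd.DataFrame(
        {
            "label": [r.label for r in results],
            "n_left": [r.n_left for r in results],
            "n_right": [r.n_right for r in results],
            "n_total": [r.n_total for r in results],
            "left_fraction": [r.left_fraction for r in results],
            "z": [r.z for r in results],
            "significant": [r.significant for r in results],
        }
    )


def reference_laterality_frame(z_threshold: float = DEFAULT_SYMMETRY_Z_THRESHOLD) -> pd.DataFrame:
    """Recompute lateralization statistics from the shipped 2012 tallies."""
    rows = []
    for (domain, name), (nl, nr) in LATERALITY_COUNTS_2012.items():
        z = symmetry_z(nl, nr)
        rows.append(
            {
                "subdomain": name,
                "domain": domain,
                "n_left": nl,
                "n_right": nr,
                "n_total": nl + nr,
                "left_fraction": nl / (nl + nr),
                "z": z,
                "significant": bool(abs(z) >= z_threshold),
            }
        )
    return pd.DataFrame(rows)
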