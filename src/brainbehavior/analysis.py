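"""Regional behavior profiles: the core enrichment statistic.

For an ROI and each behavioral sub-domain *b*:

* observed probability ``p_o`` — the sum of the sub-domain's probability
  density over the ROI voxels, i.e. the fraction of that behavior's reported
  foci falling inside the ROI;
* expected probability ``p_e`` — the ROI-to-brain volume ratio, the value
  p_o would take if foci were spatially uniform within the brain;
* effect size ``p_o - p_e`` and relative probability ``(p_o - p_e)/p_e``;
* a z-score from the binomial model with N_b trials and success
  probabilities p_o (observed) and p_e (null)::

      z = (p_o - p_e) / sqrt((p_o (1 - p_o) + p_e (1 - p_e)) / N_b)

A sub-domain is flagged significant when its effect is positive and
z >= 3.0 (a Bonferroni-style guard for the 51 simultaneous tests).  ROI
voxels outside the supplied brain mask are excluded from both the density
sum and the volume ratio, keeping numerator and denominator consistent.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__ as _version
from .pdf import BehaviorPDF4D
from .roi import ROIMask, mask_volume

logger = logging.getLogger(__name__)

DEFAULT_Z_THRESHOLD = 3.0


def effect_z(p_o: float, p_e: float, n_b: int) -> float:
    """Binomial-model z-score for the effect size p_o - p_e.

    Degenerate cases: N_b = 0 returns NaN (undefined); zero variance with a
    zero effect (p_o = p_e in {0, 1}) returns 0; zero variance with a
    nonzero effect returns signed infinity.
    """
    if n_b is None or n_b <= 0:
        return float("nan")
    if not (0.0 <= p_o <= 1.0 and 0.0 <= p_e <= 1.0):
        raise ValueError("probabilities must lie in [0, 1]")
    effect = p_o - p_e
    var = (p_o * (1.0 - p_o) + p_e * (1.0 - p_e)) / n_b
    if var == 0.0:
        if effect == 0.0:
            return 0.0
        return math.copysign(float("inf"), effect)
    return effect / math.sqrt(var)


def observed_probability(pdf: BehaviorPDF4D, roi: ROIMask, subdomain_id: int) -> float:
    """Sum of one sub-domain's PDF over the ROI (fraction of its foci inside)."""
    if not pdf.grid.close_to(roi.grid):
        raise ValueError(
            "ROI grid does not match the PDF grid; resample the ROI first "
            "(roi.resample_mask / transform.apply_to_mask)"
        )
    i = pdf.channel_index(subdomain_id)
    n_b = int(pdf.n_foci[i])
    if n_b == 0:
        return 0.0
    inside = int(pdf.counts[..., i][roi.data].sum())
    return min(1.0, max(0.0, inside / n_b))


def expected_probability(roi: ROIMask, brain_mask: ROIMask) -> float:
    """ROI-to-brain volume ratio (ROI clipped to the brain mask)."""
    if not roi.grid.close_to(brain_mask.grid):
        raise ValueError("ROI and brain mask are on different grids; resample first")
    n_brain = brain_mask.n_voxels
    if n_brain == 0:
        raise ValueError("brain mask is empty; expected probability is undefined")
    inside = int((roi.data & brain_mask.data).sum())
    outside = roi.n_voxels - inside
    if outside:
        logger.warning("%d ROI voxels fall outside the brain mask and are ignored", outside)
    return inside / n_brain


@dataclass(frozen=True)
class ProfileRow:
    """Per-sub-domain statistics of a behavior profile."""

    subdomain_id: int
    domain: str
    name: str
    n_foci: int
    foci_in_roi: int
    p_obs: float
    p_exp: float
    effect: float
    rel_prob: float
    z: float
    significant: bool


@dataclass
class BehaviorProfile:
    """Ranked 51-row behavior profile for one ROI."""

    rows: list[ProfileRow]
    z_threshold: float = DEFAULT_Z_THRESHOLD
    brain_volume_mm3: float = float("nan")
    roi_provenance: str = ""

    def significant_ids(self) -> tuple[int, ...]:
        return tuple(r.subdomain_id for r in self.rows if r.significant)

    def row_for(self, subdomain_id: int) -> ProfileRow:
        for r in self.rows:
            if r.subdomain_id == subdomain_id:
                return r
        raise KeyError(f"no row for sub-domain {subdomain_id}")

    def rank_of(self, subdomain_id: int) -> int:
        """1-based position of a sub-domain in the ranked profile."""
        for pos, r in enumerate(self.rows, start=1):
            if r.subdomain_id == subdomain_id:
                return pos
        raise KeyError(f"no row for sub-domain {subdomain_id}")

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame([vars(r) for r in self.rows])
        df.insert(0, "rank", np.arange(1, len(df) + 1))
        return df

    def __eq__(self, other) -> bool:
        if not isinstance(other, BehaviorProfile):
            return NotImplemented

        def key(p):
            return (
                [(r.subdomain_id, r.n_foci, r.foci_in_roi) for r in p.rows],
                [(r.p_obs, r.p_exp, r.z) for r in p.rows],
                p.z_threshold,
            )

        a, b = key(self), key(other)
        if a[0] != b[0] or a[2] != b[2]:
            return False
        return np.allclose(np.nan_to_num(np.array(a[1], dtype=float), nan=-1e300),
                           np.nan_to_num(np.array(b[1], dtype=float), nan=-1e300),
                           rtol=0, atol=1e-12)


def _rank_key(row: ProfileRow):
    z = row.z
    zkey = -float("inf") if (z is None or math.isnan(z)) else z
    return (-zkey, row.subdomain_id)


def analyze(
    pdf: BehaviorPDF4D,
    roi: ROIMask,
    brain_mask: ROIMask,
    z_threshold: float = DEFAULT_Z_THRESHOLD,
) -> BehaviorProfile:
    """Compute the full ranked behavior profile of an ROI.

    All three inputs must share one grid (resample first otherwise).  The
    ROI is clipped to the brain mask for both the observed and the expected
    probability.  ``foci_in_roi`` is derived as round(p_o * N_b), matching
    the PDF-sum pathway rather than a separate tally.
    """
    if not pdf.grid.close_to(roi.grid) or not pdf.grid.close_to(brain_mask.grid):
        raise ValueError(
            "PDF, ROI and brain mask must share a grid; resample the ROI/brain "
            "mask to the PDF grid first"
        )
    roi_in_brain = roi.data & brain_mask.data
    clipped = ROIMask(roi.grid, roi_in_brain, provenance=roi.provenance)
    p_e = expected_probability(clipped, brain_mask)

    inside = pdf.counts[roi_in_brain, :].sum(axis=0, dtype=np.int64)
    rows = []
    for i, sub in enumerate(pdf.taxonomy.subdomains):
        n_b = int(pdf.n_foci[i])
        if n_b > 0:
            p_o = min(1.0, max(0.0, int(inside[i]) / n_b))
            z = effect_z(p_o, p_e, n_b)
        else:
            p_o = 0.0
            z = float("nan")
        effect = p_o - p_e
        if p_e > 0:
            rel = effect / p_e
        else:
            rel = float("nan") if effect == 0 else math.copysign(float("inf"), effect)
        significant = bool(n_b > 0 and effect > 0 and z >= z_threshold)
        rows.append(
            ProfileRow(
                subdomain_id=sub.id,
                domain=sub.domain,
                name=sub.name,
                n_foci=n_b,
                foci_in_roi=int(round(p_o * n_b)),
                p_obs=p_o,
                p_exp=p_e,
                effect=effect,
                rel_prob=rel,
                z=z,
                significant=significant,
            )
        )
    rows.sort(key=_rank_key)
    return BehaviorProfile(
        rows=rows,
        z_threshold=z_threshold,
        brain_volume_mm3=mask_volume(brain_mask),
        roi_provenance=roi.provenance,
    )


# ---------------------------------------------------------------------------
# Export / import

def export_profile(profile: BehaviorProfile, path: str | Path, format: str = "csv") -> None:
    """Write a ranked profile as CSV (with provenance comments) or JSON."""
    path = Path(path)
    if format == "csv":
        with open(path, "w", newline="") as fh:
            fh.write(f"# brainbehavior {_version}\n")
            fh.write(f"# roi: {profile.roi_provenance}\n")
            fh.write(f"# z_threshold: {profile.z_threshold}; "
                     f"brain_volume_mm3: {profile.brain_volume_mm3}\n")
            profile.to_frame().to_csv(fh, index=False)
    elif format == "json":
        payload = {
            "tool": f"brainbehavior {_version}",
            "z_threshold": profile.z_threshold,
            "brain_volume_mm3": profile.brain_volume_mm3,
            "roi_provenance": profile.roi_provenance,
            "rows": [vars(r) for r in profile.rows],
        }
        path.write_text(json.dumps(payload, indent=1, default=float))
    else:
        raise ValueError("format must be 'csv' or 'json'")


def read_profile(path: str | Path) -> BehaviorProfile:
    """Read back a profile exported as JSON."""
    payload = json.loads(Path(path).read_text())
    rows = [ProfileRow(**{**r, "z": float(r["z"]) if r["z"] is not None else float("nan")})
            for r in payload["rows"]]
    return BehaviorProfile(
        rows=rows,
        z_threshold=payload["z_threshold"],
        brain_volume_mm3=payload["brain_volume_mm3"],
        roi_provenance=payload.get("roi_provenance", ""),
    )


def plot_profile(profile: BehaviorProfile, path: str | Path, top: int = 51) -> None:
    """Render the ranked profile as a horizontal z-score bar chart."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    rows = [r for r in profile.rows if not math.isnan(r.z)][:top]
    labels = [f"{r.domain}:{r.name}" for r in rows]
    zs = [r.z for r in rows]
    colors = ["tab:red" if r.significant else "tab:gray" for r in rows]
    fig, ax = plt.subplots(figsize=(7, max(2, 0.22 * len(rows))))
    ax.barh(range(len(rows))[::-1], zs, color=colors)
    ax.set_yticks(range(len(rows))[::-1], labels, fontsize=6)
    ax.axvline(profile.z_threshold, color="k", ls="--", lw=0.8)
    ax.set_xlabel("z-score")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
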