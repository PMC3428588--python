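"""Synthetic foci tables and brain masks with known ground truth.

Real coordinate databases are access-restricted, so every stage of the
pipeline is exercised against generated data whose structure emulates them:
51 behavioral sub-domains, per-sub-domain focus totals matching the 2012
snapshot tallies by default, spatial clustering (isotropic Gaussian clusters
truncated to the brain by rejection), a uniform in-brain component, and an
optional hemispheric bias implemented by reflecting foci across the
midsagittal plane.  The brain is an ellipsoid centered at the origin with
semi-axes (70, 85, 65) mm by default, approximating atlas brain extent and
volume (~1.6e6 mm^3).

All draws come from a seeded ``numpy.random.default_rng`` stream, so a given
seed reproduces a table exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from types import SimpleNamespace

import numpy as np
import pandas as pd
import yaml

from .foci import FociTable, FocusRecord
from .grid import DEFAULT_BOUNDS, GridSpec, make_grid
from .roi import ROIMask, roi_sphere
from .taxonomy import default_focus_counts, load_taxonomy

DEFAULT_BRAIN_SEMI_AXES = (70.0, 85.0, 65.0)


@dataclass(frozen=True)
class Cluster:
    """One Gaussian focus cluster: center (mm), isotropic sd (mm), weight."""

    center: tuple[float, float, float]
    sd: float
    weight: float

    def __post_init__(self) -> None:
        if self.sd <= 0:
            raise ValueError("cluster sd must be positive")
        if self.weight < 0:
            raise ValueError("cluster weight must be non-negative")


@dataclass(frozen=True)
class SubdomainSimSpec:
    """Simulation recipe for one behavioral sub-domain."""

    subdomain_id: int
    n_foci: int
    clusters: tuple[Cluster, ...] = ()
    uniform_fraction: float = 1.0
    left_bias: float | None = None

    def __post_init__(self) -> None:
        if self.n_foci < 0:
            raise ValueError("n_foci must be >= 0")
        total = sum(c.weight for c in self.clusters) + self.uniform_fraction
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError("cluster weights + uniform_fraction must sum to 1")
        if self.left_bias is not None and not (0.0 <= self.left_bias <= 1.0):
            raise ValueError("left_bias must lie in [0, 1]")


def generate_brain_mask(
    grid: GridSpec, semi_axes=DEFAULT_BRAIN_SEMI_AXES, center=(0.0, 0.0, 0.0)
) -> ROIMask:
    """Ellipsoid brain mask: voxel centers with sum((c_i/a_i)^2) <= 1."""
    a = np.asarray(semi_axes, dtype=float)
    if np.any(a <= 0):
        raise ValueError("semi-axes must be positive")
    q = np.zeros(grid.shape)
    for ax in range(3):
        d = (grid.axis_coords(ax) - center[ax]) / a[ax]
        shape = [1, 1, 1]
        shape[ax] = -1
        q = q + (d ** 2).reshape(shape)
    return ROIMask(grid, q <= 1.0, provenance=f"ellipsoid brain {tuple(a)}mm")


def _coords_in_mask(coords: np.ndarray, mask: ROIMask) -> np.ndarray:
    idx, in_grid = mask.grid.coord_to_voxel(coords)
    ok = in_grid.copy()
    if in_grid.any():
        flat = np.ravel_multi_index(idx[in_grid].T, mask.grid.shape)
        ok[in_grid] = mask.data.ravel()[flat]
    return ok


def _mask_bbox_mm(mask: ROIMask) -> tuple[np.ndarray, np.ndarray]:
    set_idx = np.argwhere(mask.data)
    if len(set_idx) == 0:
        raise ValueError("cannot sample from an empty mask")
    half = mask.grid.spacing / 2.0
    lo = mask.grid.voxel_to_coord(set_idx.min(axis=0)) - half
    hi = mask.grid.voxel_to_coord(set_idx.max(axis=0)) + half
    return lo, hi


def _rejection_sample(n: int, draw, accept, max_rounds: int = 1000) -> np.ndarray:
    """Draw until ``n`` accepted samples; ``draw(m)`` proposes, ``accept`` filters."""
    out = np.empty((0, 3))
    rounds = 0
    while len(out) < n:
        m = max(2 * (n - len(out)), 16)
        prop = draw(m)
        kept = prop[accept(prop)]
        if len(kept):
            out = np.vstack([out, kept])
        rounds += 1
        if rounds > max_rounds:
            raise RuntimeError("rejection sampling failed to hit the mask; check geometry")
    return out[:n]


def generate_foci(
    specs, brain_mask: ROIMask, seed: int, space: str = "TAL"
) -> tuple[FociTable, pd.DataFrame]:
    """Generate a foci table from per-sub-domain recipes.

    Returns the table plus a ground-truth frame with one row per focus
    recording its sub-domain and source component (cluster index, or -1 for
    the uniform component).  Foci are guaranteed to lie inside the brain
    mask (cluster draws are redrawn until they land inside: a truncated
    Gaussian).  With ``left_bias`` set, each focus is reflected to x < 0
    with that probability and to x > 0 otherwise (x == 0 untouched).
    """
    rng = np.random.default_rng(seed)
    taxonomy = load_taxonomy()
    lo, hi = _mask_bbox_mm(brain_mask)
    table = FociTable(taxonomy=taxonomy)
    truth_rows: list[tuple[int, int]] = []

    for spec in specs:
        sid = taxonomy.by_id(spec.subdomain_id).id
        if spec.n_foci == 0:
            continue
        weights = [c.weight for c in spec.clusters] + [spec.uniform_fraction]
        components = rng.choice(len(weights), size=spec.n_foci, p=weights)
        coords = np.empty((spec.n_foci, 3))
        for comp in range(len(weights)):
            sel = components == comp
            n_comp = int(sel.sum())
            if n_comp == 0:
                continue
            if comp < len(spec.clusters):
                cl = spec.clusters[comp]
                center = np.asarray(cl.center, dtype=float)

                def draw(m, _c=center, _sd=cl.sd):
                    return rng.normal(_c, _sd, size=(m, 3))
            else:

                def draw(m):
                    return rng.uniform(lo, hi, size=(m, 3))

            coords[sel] = _rejection_sample(
                n_comp, draw, lambda c: _coords_in_mask(c, brain_mask)
            )
        if spec.left_bias is not None:
            to_left = rng.random(spec.n_foci) < spec.left_bias
            x = np.abs(coords[:, 0])
            coords[:, 0] = np.where(to_left, -x, x)
        for (x, y, z), comp in zip(coords, components):
            table.append(FocusRecord(f"sim-{sid:02d}", sid, float(x), float(y), float(z), space))
            truth_rows.append((sid, int(comp) if comp < len(spec.clusters) else -1))

    truth = pd.DataFrame(truth_rows, columns=["subdomain", "component"])
    return table, truth


def uniform_specs(
    ids=None, counts: dict[int, int] | None = None, left_bias: float | None = None
) -> list[SubdomainSimSpec]:
    """Spatially uniform recipes, defaulting to the 2012 snapshot scales."""
    counts = counts or default_focus_counts(ids)
    return [
        SubdomainSimSpec(sid, n, uniform_fraction=1.0, left_bias=left_bias)
        for sid, n in counts.items()
    ]


def specs_from_yaml(path) -> tuple[list[SubdomainSimSpec], dict]:
    """Load simulation recipes (and optional brain/grid config) from YAML.

    Schema::

        brain: {semi_axes: [70, 85, 65], spacing: 2}
        subdomains:
          - id: 14
            n_foci: 7593
            uniform_fraction: 0.2
            left_bias: 0.6
            clusters:
              - {center: [-44, 16, 12], sd: 8, weight: 0.8}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    specs = []
    for entry in cfg.get("subdomains", []):
        clusters = tuple(
            Cluster(tuple(c["center"]), float(c["sd"]), float(c["weight"]))
            for c in entry.get("clusters", ())
        )
        specs.append(
            SubdomainSimSpec(
                subdomain_id=int(entry["id"]),
                n_foci=int(entry["n_foci"]),
                clusters=clusters,
                uniform_fraction=float(entry.get("uniform_fraction",
                                                 1.0 - sum(c.weight for c in clusters))),
                left_bias=entry.get("left_bias"),
            )
        )
    return specs, cfg.get("brain", {})


def known_answer_suite(seed: int, spacing: float = 2.0) -> SimpleNamespace:
    """Canonical fixtures with known qualitative outcomes.

    * ``recovery`` — one tightly clustered sub-domain (id 1, at a motor-
      cortex-like site) among 50 uniform ones, all at 2012-snapshot scales,
      with a 12-mm spherical ROI over the cluster: exactly that sub-domain
      should be significant and ranked first.
    * ``lateralized`` — one sub-domain (id 14) with a 60/40 leftward bias at
      n = 2000: flagged leftward at |z| >= 3 (closed-form z ~ 9.1).
    * ``disjoint`` — three sub-domains (ids 10, 30, 43) with disjoint tight
      clusters: the self-consistency rank matrix should have an all-ones
      diagonal with large diagonal z.
    """
    grid = make_grid(spacing)
    brain = generate_brain_mask(grid)
    rng_seeds = np.random.SeedSequence(seed).spawn(3)

    cluster_center = (-32.0, -24.0, 48.0)
    recovery_specs = [
        SubdomainSimSpec(1, default_focus_counts([1])[1],
                         clusters=(Cluster(cluster_center, 6.0, 1.0),),
                         uniform_fraction=0.0)
    ] + uniform_specs(ids=[i for i in load_taxonomy().ids() if i != 1])
    recovery_foci, recovery_truth = generate_foci(
        recovery_specs, brain, seed=int(rng_seeds[0].generate_state(1)[0] % (2**31))
    )
    recovery_roi = roi_sphere(cluster_center, 12.0, grid)

    lateralized_specs = [SubdomainSimSpec(14, 2000, uniform_fraction=1.0, left_bias=0.6)]
    lateralized_foci, _ = generate_foci(
        lateralized_specs, brain, seed=int(rng_seeds[1].generate_state(1)[0] % (2**31))
    )

    disjoint_specs = [
        SubdomainSimSpec(10, 1000, clusters=(Cluster((-40.0, -20.0, 40.0), 5.0, 1.0),),
                         uniform_fraction=0.0),
        SubdomainSimSpec(30, 1000, clusters=(Cluster((40.0, 20.0, -40.0), 5.0, 1.0),),
                         uniform_fraction=0.0),
        SubdomainSimSpec(43, 1000, clusters=(Cluster((0.0, 60.0, 0.0), 5.0, 1.0),),
                         uniform_fraction=0.0),
    ]
    disjoint_foci, _ = generate_foci(
        disjoint_specs, brain, seed=int(rng_seeds[2].generate_state(1)[0] % (2**31))
    )

    return SimpleNamespace(
        grid=grid,
        brain=brain,
        recovery=SimpleNamespace(foci=recovery_foci, truth=recovery_truth,
                                 roi=recovery_roi, target=1),
        lateralized=SimpleNamespace(foci=lateralized_foci, target=14, bias=0.6),
        disjoint=SimpleNamespace(foci=disjoint_foci, targets=(10, 30, 43)),
    )
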