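"""Foci tables: stereotaxic activation coordinates labelled by behavior.

A foci table is the flat record of (experiment, sub-domain, x, y, z) rows
that coordinate-based databases export.  The same coordinate may legitimately
appear under several sub-domains because experiments carry multiple behavior
codes; each (coordinate, sub-domain) pairing is kept as its own record, and
exact duplicate rows are retained — downstream tallies count reported foci,
not unique locations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .taxonomy import BehaviorTaxonomy, load_taxonomy

logger = logging.getLogger(__name__)

SPACE_TAGS = ("TAL", "MNI")

_EXPERIMENT_ALIASES = ("experiment", "experiment_id", "study", "exp")
_SUBDOMAIN_ALIASES = ("subdomain", "subdomain_id", "behavior", "behavior_id")
_SPACE_ALIASES = ("space", "space_tag")


@dataclass(frozen=True)
class FocusRecord:
    """A single activation focus in millimetre stereotaxic coordinates."""

    experiment_id: str
    subdomain_id: int
    x: float
    y: float
    z: float
    space: str = "TAL"

    @property
    def coord(self) -> tuple[float, float, float]:
        return (self.x, self.y, self.z)


class FociTable:
    """Ordered collection of :class:`FocusRecord` with a per-sub-domain index."""

    def __init__(
        self,
        records: Iterable[FocusRecord] = (),
        taxonomy: BehaviorTaxonomy | None = None,
    ) -> None:
        self.taxonomy = taxonomy or load_taxonomy()
        self.records: list[FocusRecord] = []
        self._index: dict[int, list[int]] = {}
        for rec in records:
            self.append(rec)

    def append(self, rec: FocusRecord) -> None:
        if rec.subdomain_id not in self.taxonomy:
            raise KeyError(f"unknown sub-domain id {rec.subdomain_id}")
        if not all(np.isfinite([rec.x, rec.y, rec.z])):
            raise ValueError(f"non-finite coordinate in record {rec}")
        if rec.space not in SPACE_TAGS:
            raise ValueError(f"unknown space tag {rec.space!r}")
        self._index.setdefault(rec.subdomain_id, []).append(len(self.records))
        self.records.append(rec)

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def __eq__(self, other) -> bool:
        return isinstance(other, FociTable) and self.records == other.records

    @property
    def subdomain_ids(self) -> tuple[int, ...]:
        """Sub-domains with at least one record, in taxonomy order."""
        return tuple(i for i in self.taxonomy.ids() if i in self._index)

    def coords_for(self, subdomain_id: int) -> np.ndarray:
        """(n, 3) mm coordinates for one sub-domain, in row order."""
        idx = self._index.get(int(subdomain_id), [])
        if not idx:
            return np.empty((0, 3), dtype=float)
        return np.array([self.records[i].coord for i in idx], dtype=float)

    def per_subdomain_counts(self) -> dict[int, int]:
        return {i: len(self._index[i]) for i in self.subdomain_ids}

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "experiment": [r.experiment_id for r in self.records],
                "subdomain": [r.subdomain_id for r in self.records],
                "x": [r.x for r in self.records],
                "y": [r.y for r in self.records],
                "z": [r.z for r in self.records],
                "space": [r.space for r in self.records],
            }
        )

    def transformed(self, coords: np.ndarray, space: str = "TAL") -> "FociTable":
        """Copy of the table with coordinates replaced (e.g. after MNI->TAL)."""
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.records), 3):
            raise ValueError("coordinate array shape does not match table")
        out = FociTable(taxonomy=self.taxonomy)
        for rec, (x, y, z) in zip(self.records, coords):
            out.append(
                FocusRecord(rec.experiment_id, rec.subdomain_id, float(x), float(y), float(z), space)
            )
        return out


def _find_column(columns: Sequence[str], aliases: Sequence[str], what: str) -> str:
    lowered = {c.lower().strip(): c for c in columns}
    for alias in aliases:
        if alias in lowered:
            return lowered[alias]
    raise ValueError(f"foci table is missing a {what} column (one of {aliases})")


def read_foci_table(
    path: str | Path,
    space_tag: str | None = None,
    taxonomy: BehaviorTaxonomy | None = None,
) -> FociTable:
    """Read a delimited-text foci table (comma or tab separated, with header).

    The sub-domain column may hold integer ids or ``Domain:Name`` strings;
    both are normalized to ids.  ``space_tag`` overrides any per-row space
    column; when neither is present, Talairach is assumed.
    """
    taxonomy = taxonomy or load_taxonomy()
    import csv as _csv

    try:
        df = pd.read_csv(path, sep=None, engine="python", comment="#", dtype=str,
                         skip_blank_lines=True)
    except pd.errors.EmptyDataError:
        return FociTable(taxonomy=taxonomy)
    except _csv.Error:
        # the delimiter sniffer cannot handle a bare header / empty file
        if not Path(path).read_text().strip():
            return FociTable(taxonomy=taxonomy)
        df = pd.read_csv(path, comment="#", dtype=str, skip_blank_lines=True)
    if df.empty and len(df.columns) <= 1:
        # header-only single-column file
        return FociTable(taxonomy=taxonomy)
    exp_col = _find_column(df.columns, _EXPERIMENT_ALIASES, "experiment id")
    sub_col = _find_column(df.columns, _SUBDOMAIN_ALIASES, "sub-domain")
    for axis in "xyz":
        _find_column(df.columns, (axis,), f"{axis} coordinate")
    cols = {c.lower().strip(): c for c in df.columns}
    space_col = next((cols[a] for a in _SPACE_ALIASES if a in cols), None)

    table = FociTable(taxonomy=taxonomy)
    for pos, (_, row) in enumerate(df.iterrows(), start=2):  # 1-based + header
        try:
            sid = taxonomy.resolve(row[sub_col])
        except KeyError as exc:
            raise ValueError(f"row {pos} of {path}: {exc.args[0]}") from None
        try:
            x, y, z = (float(row[cols[a]]) for a in "xyz")
        except (TypeError, ValueError):
            raise ValueError(
                f"row {pos} of {path}: non-numeric coordinate "
                f"({row[cols['x']]!r}, {row[cols['y']]!r}, {row[cols['z']]!r})"
            ) from None
        space = space_tag or (str(row[space_col]).strip() if space_col else "TAL")
        table.append(FocusRecord(str(row[exp_col]), sid, x, y, z, space))
    return table


def write_foci_table(table: FociTable, path: str | Path, sep: str = ",") -> None:
    """Write a foci table; ``read_foci_table`` reproduces it record-for-record."""
    df = table.to_frame()
    df.to_csv(path, sep=sep, index=False)
    logger.info("wrote %d foci records to %s", len(table), path)
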