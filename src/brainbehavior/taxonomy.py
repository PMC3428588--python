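"""Behavioral taxonomy used to classify functional-imaging experiments.

The BrainMap coding scheme organises behavior into five major domains
(Action, Cognition, Emotion, Interoception, Perception) subdivided into 51
sub-domains.  Each sub-domain carries an integer id (1-51) that indexes the
channels of the 4-D behavioral probability image.  Behaviors that fit a
domain but no specific sub-domain are coded ``Other`` at the appropriate
level (e.g. ``Action:Other``, ``Perception:Vision:Other``).
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path
from typing import Iterable

DOMAINS: tuple[str, ...] = (
    "Action",
    "Cognition",
    "Emotion",
    "Interoception",
    "Perception",
)

# (id, domain, sub-domain name)
_SUBDOMAIN_ROWS: tuple[tuple[int, str, str], ...] = (
    (1, "Action", "Execution:Other"),
    (2, "Action", "Execution:Speech"),
    (3, "Action", "Imagination"),
    (4, "Action", "Inhibition"),
    (5, "Action", "Motor:Learning"),
    (6, "Action", "Observation"),
    (7, "Action", "Other"),
    (8, "Action", "Preparation"),
    (9, "Action", "Rest"),
    (10, "Cognition", "Attention"),
    (11, "Cognition", "Language:Orthography"),
    (12, "Cognition", "Language:Other"),
    (13, "Cognition", "Language:Phonology"),
    (14, "Cognition", "Language:Semantics"),
    (15, "Cognition", "Language:Speech"),
    (16, "Cognition", "Language:Syntax"),
    (17, "Cognition", "Memory:Explicit"),
    (18, "Cognition", "Memory:Other"),
    (19, "Cognition", "Memory:Working"),
    (20, "Cognition", "Music"),
    (21, "Cognition", "Other"),
    (22, "Cognition", "Reasoning"),
    (23, "Cognition", "Social"),
    (24, "Cognition", "Soma"),
    (25, "Cognition", "Space"),
    (26, "Cognition", "Time"),
    (27, "Emotion", "Anger"),
    (28, "Emotion", "Anxiety"),
    (29, "Emotion", "Disgust"),
    (30, "Emotion", "Fear"),
    (31, "Emotion", "Happiness:Humor"),
    (32, "Emotion", "Happiness:Other"),
    (33, "Emotion", "Other"),
    (34, "Emotion", "Sadness"),
    (35, "Interoception", "Air-hunger"),
    (36, "Interoception", "Bladder"),
    (37, "Interoception", "Hunger"),
    (38, "Interoception", "Other"),
    (39, "Interoception", "Sexuality"),
    (40, "Interoception", "Sleep"),
    (41, "Interoception", "Thermoregulation"),
    (42, "Interoception", "Thirst"),
    (43, "Perception", "Audition"),
    (44, "Perception", "Gustation"),
    (45, "Perception", "Olfaction"),
    (46, "Perception", "Somesthesis:Other"),
    (47, "Perception", "Somesthesis:Pain"),
    (48, "Perception", "Vision:Color"),
    (49, "Perception", "Vision:Motion"),
    (50, "Perception", "Vision:Other"),
    (51, "Perception", "Vision:Shape"),
)

#: Whole-brain focus tallies per sub-domain in the 2012 BrainMap snapshot.
#: Descriptive of that database release, not a constant of the method; used
#: as the default per-sub-domain scale of the synthetic foci generator.
SUBDOMAIN_FOCUS_COUNTS_2012: dict[int, int] = {
    1: 8518, 2: 3399, 3: 1244, 4: 2519, 5: 832, 6: 972, 7: 11, 8: 346,
    9: 1611, 10: 10995, 11: 2011, 12: 1204, 13: 1621, 14: 7593, 15: 7244,
    16: 655, 17: 7002, 18: 50, 19: 7819, 20: 822, 21: 8847, 22: 1387,
    23: 1562, 24: 581, 25: 1935, 26: 495, 27: 507, 28: 577, 29: 879,
    30: 1311, 31: 120, 32: 1060, 33: 12821, 34: 1167, 35: 236, 36: 315,
    37: 386, 38: 200, 39: 877, 40: 260, 41: 29, 42: 209, 43: 2850,
    44: 1173, 45: 400, 46: 2542, 47: 3472, 48: 201, 49: 2514, 50: 2106,
    51: 2995,
}


@dataclass(frozen=True)
class Subdomain:
    """One behavioral sub-domain: integer id, parent domain, name."""

    id: int
    domain: str
    name: str

    @property
    def full_name(self) -> str:
        return f"{self.domain}:{self.name}"


@dataclass(frozen=True)
class BehaviorTaxonomy:
    """The fixed 5-domain / 51-sub-domain behavioral classification."""

    domains: tuple[str, ...]
    subdomains: tuple[Subdomain, ...]
    _by_id: dict[int, Subdomain] = field(repr=False, default_factory=dict)

    def __post_init__(self) -> None:
        by_id = {s.id: s for s in self.subdomains}
        if len(by_id) != len(self.subdomains):
            raise ValueError("duplicate sub-domain ids")
        for s in self.subdomains:
            if s.domain not in self.domains:
                raise ValueError(f"sub-domain {s.id} has unknown domain {s.domain!r}")
        object.__setattr__(self, "_by_id", by_id)

    def __len__(self) -> int:
        return len(self.subdomains)

    def ids(self) -> tuple[int, ...]:
        return tuple(s.id for s in self.subdomains)

    def by_id(self, subdomain_id: int) -> Subdomain:
        try:
            return self._by_id[int(subdomain_id)]
        except KeyError:
            raise KeyError(f"unknown sub-domain id {subdomain_id}") from None

    def __contains__(self, subdomain_id: int) -> bool:
        return int(subdomain_id) in self._by_id

    def channel_index(self, subdomain_id: int) -> int:
        """Position of a sub-domain in taxonomy (and 4-D channel) order."""
        return self.ids().index(self.by_id(subdomain_id).id)

    def in_domain(self, domain: str) -> tuple[Subdomain, ...]:
        return tuple(s for s in self.subdomains if s.domain == domain)

    def resolve(self, label: int | str) -> int:
        """Normalize a sub-domain given as id, ``Domain:Name`` or bare name.

        Raises ``KeyError`` for anything that does not identify exactly one
        sub-domain (bare ``Other`` is ambiguous, for example).
        """
        if isinstance(label, (int,)) or (
            isinstance(label, str) and label.strip().lstrip("-").isdigit()
        ):
            sid = int(label)
            return self.by_id(sid).id
        text = str(label).strip()
        matches = [s for s in self.subdomains if s.full_name == text]
        if not matches:
            matches = [s for s in self.subdomains if s.name == text]
        if len(matches) == 1:
            return matches[0].id
        if len(matches) > 1:
            raise KeyError(f"ambiguous sub-domain label {label!r}")
        raise KeyError(f"unknown sub-domain label {label!r}")

    def to_csv(self, path: str | Path) -> None:
        """Export the taxonomy as a small CSV for documentation."""
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(["id", "domain", "name"])
            for s in self.subdomains:
                writer.writerow([s.id, s.domain, s.name])


@lru_cache(maxsize=1)
def load_taxonomy() -> BehaviorTaxonomy:
    """Return the fixed behavioral taxonomy (51 sub-domains, 5 domains)."""
    subs = tuple(Subdomain(i, d, n) for i, d, n in _SUBDOMAIN_ROWS)
    return BehaviorTaxonomy(domains=DOMAINS, subdomains=subs)


def default_focus_counts(ids: Iterable[int] | None = None) -> dict[int, int]:
    """Per-sub-domain focus tallies of the 2012 database snapshot."""
    if ids is None:
        return dict(SUBDOMAIN_FOCUS_COUNTS_2012)
    return {int(i): SUBDOMAIN_FOCUS_COUNTS_2012[int(i)] for i in ids}
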