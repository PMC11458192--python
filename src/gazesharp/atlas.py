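"""Joint inventory for the modified van der Heijde Sharp (mvdH) score.

The mvdH score grades structural damage in rheumatoid arthritis on hand and
foot radiographs, per joint and per lesion type: *erosion* (cortical bone
destruction, graded 0-5 per hand joint and 0-10 per foot joint) and *joint
space narrowing* (JSN, cartilage loss, graded 0-4 everywhere).  Per patient,
16 hand sites per hand are scored for erosion, 15 per hand for JSN, and 6
sites per foot for both lesions.

This module defines that inventory as plain data: :class:`JointSite`,
:class:`Atlas`, and :func:`build_default_atlas`.  Enumeration order is fixed
(hands before feet, right before left, anatomical row order within a region)
so that every downstream file artifact is reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable


class Region(str, Enum):
    HAND = "hand"
    FOOT = "foot"


class Side(str, Enum):
    RIGHT = "right"
    LEFT = "left"


class Lesion(str, Enum):
    EROSION = "erosion"
    JSN = "jsn"


#: Score caps per mvdH convention: erosions saturate at 5 per hand joint and
#: 10 per foot joint; JSN saturates at 4 everywhere.
MAX_EROSION_HAND = 5
MAX_EROSION_FOOT = 10
MAX_JSN = 4

# Hand sites scored for erosion (16 per hand): distal radius and ulna, four
# wrist bones incl. the first metacarpal base, the five MCPs and the five
# proximal interphalangeal joints (thumb IP counted as IPP1).
HAND_EROSION_NAMES = (
    "Radius",
    "Ulna",
    "Scaphoïd",
    "Lunatum",
    "Trapezium",
    "M1 base",
    "MCP1",
    "MCP2",
    "MCP3",
    "MCP4",
    "MCP5",
    "IPP1",
    "IPP2",
    "IPP3",
    "IPP4",
    "IPP5",
)

# Hand sites scored for JSN (15 per hand): three wrist articulations, the
# 3rd-5th carpometacarpal joints, the five MCPs and IPP2-5.  The thumb IP is
# not a JSN site in the mvdH convention.
HAND_JSN_NAMES = (
    "Scaphoïd-radius",
    "Scaphoïd-Capitatum",
    "Scaphoïd-Trapezium",
    "MCC3",
    "MCC4",
    "MCC5",
    "MCP1",
    "MCP2",
    "MCP3",
    "MCP4",
    "MCP5",
    "IPP2",
    "IPP3",
    "IPP4",
    "IPP5",
)

# Foot sites (6 per foot), each scored for both erosion and JSN.
FOOT_NAMES = (
    "IP1 foot",
    "MTP1",
    "MTP2",
    "MTP3",
    "MTP4",
    "MTP5",
)


@dataclass(frozen=True)
class JointSite:
    """One scoreable anatomical site on one side of one region.

    ``site_id`` is the opaque stable key (``"hand:right:MCP2"``) used by ROI
    layouts, fixation summaries and score tables.
    """

    site_id: str
    region: Region
    side: Side
    name: str
    lesions: frozenset[Lesion]
    max_erosion: int
    max_jsn: int

    def scores(self, lesion: Lesion) -> bool:
        return lesion in self.lesions

    def to_dict(self) -> dict:
        return {
            "site_id": self.site_id,
            "region": self.region.value,
            "side": self.side.value,
            "name": self.name,
            "lesions": sorted(l.value for l in self.lesions),
            "max_erosion": self.max_erosion,
            "max_jsn": self.max_jsn,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "JointSite":
        return cls(
            site_id=d["site_id"],
            region=Region(d["region"]),
            side=Side(d["side"]),
            name=d["name"],
            lesions=frozenset(Lesion(l) for l in d["lesions"]),
            max_erosion=int(d["max_erosion"]),
            max_jsn=int(d["max_jsn"]),
        )


@dataclass
class Atlas:
    """Ordered per-patient collection of :class:`JointSite`."""

    sites: tuple[JointSite, ...] = field(default_factory=tuple)

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)

    def site(self, site_id: str) -> JointSite:
        try:
            return self._index[site_id]
        except AttributeError:
            self._index = {s.site_id: s for s in self.sites}
            return self._index[site_id]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps([s.to_dict() for s in self.sites], ensure_ascii=False, indent=1),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "Atlas":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(sites=tuple(JointSite.from_dict(d) for d in data))


def _site_id(region: Region, side: Side, name: str) -> str:
    return f"{region.value}:{side.value}:{name}"


def build_default_atlas() -> Atlas:
    """Build the canonical one-patient mvdH atlas (both hands, both feet).

    Deterministic: hands before feet, right before left, anatomical order
    within each region.  Yields 44 erosion-scored sites (16 x 2 hands +
    6 x 2 feet) and 42 JSN-scored sites (15 x 2 + 6 x 2) per patient.
    """
    sites: list[JointSite] = []
    for side in (Side.RIGHT, Side.LEFT):
        both = set(HAND_EROSION_NAMES) & set(HAND_JSN_NAMES)
        for name in HAND_EROSION_NAMES:
            lesions = {Lesion.EROSION} | ({Lesion.JSN} if name in both else set())
            sites.append(
                JointSite(
                    site_id=_site_id(Region.HAND, side, name),
                    region=Region.HAND,
                    side=side,
                    name=name,
                    lesions=frozenset(lesions),
                    max_erosion=MAX_EROSION_HAND,
                    max_jsn=MAX_JSN,
                )
            )
        for name in HAND_JSN_NAMES:
            if name in both:
                continue  # already present as an erosion site scoring both
            sites.append(
                JointSite(
                    site_id=_site_id(Region.HAND, side, name),
                    region=Region.HAND,
                    side=side,
                    name=name,
                    lesions=frozenset({Lesion.JSN}),
                    max_erosion=MAX_EROSION_HAND,
                    max_jsn=MAX_JSN,
                )
            )
    for side in (Side.RIGHT, Side.LEFT):
        for name in FOOT_NAMES:
            sites.append(
                JointSite(
                    site_id=_site_id(Region.FOOT, side, name),
                    region=Region.FOOT,
                    side=side,
                    name=name,
                    lesions=frozenset({Lesion.EROSION, Lesion.JSN}),
                    max_erosion=MAX_EROSION_FOOT,
                    max_jsn=MAX_JSN,
                )
            )
    return Atlas(sites=tuple(sites))


def sites_for(
    atlas: Atlas,
    region: Region | str | None = None,
    lesion: Lesion | str | None = None,
    side: Side | str | None = None,
) -> list[JointSite]:
    """Stable-ordered subset of atlas sites matching the given filters."""
    region = Region(region) if region is not None else None
    lesion = Lesion(lesion) if lesion is not None else None
    side = Side(side) if side is not None else None
    out = []
    for s in atlas:
        if region is not None and s.region != region:
            continue
        if side is not None and s.side != side:
            continue
        if lesion is not None and lesion not in s.lesions:
            continue
        out.append(s)
    return out


def score_cap(site: JointSite, lesion: Lesion | str) -> int:
    """Integer cap for ``lesion`` at ``site`` (used when rounding scores)."""
    lesion = Lesion(lesion)
    if lesion not in site.lesions:
        raise ValueError(f"site {site.site_id!r} is not scored for {lesion.value}")
    if lesion is Lesion.EROSION:
        return site.max_erosion
    return site.max_jsn
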