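"""Fixation events, fixation streams, and ROI layouts, with their file dialects.

Fixation exports are tab-separated UTF-8 with the header
``t_start_ms\\tx\\ty\\tduration_ms``, one fixation per row — the shape of a
minimal eye-tracker fixation export.  Coordinates are 0-based pixels, origin
top-left, y increasing downward; durations are positive milliseconds.

ROI layouts are JSON lists of ``{site_id, cx, cy, radius}`` circles on the
radiograph canvas (the software's areas of interest).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

EXPORT_HEADER = ("t_start_ms", "x", "y", "duration_ms")


@dataclass(frozen=True)
class FixationEvent:
    """One gaze fixation: start time, gaze point, dwell duration."""

    t_start: int  # ms
    x: float  # px
    y: float  # px
    duration_ms: int

    def __post_init__(self):
        if self.duration_ms <= 0:
            raise ValueError(f"duration_ms must be > 0, got {self.duration_ms}")


@dataclass
class FixationStream:
    """Time-ordered, non-overlapping fixations of one radiograph reading."""

    events: list[FixationEvent] = field(default_factory=list)

    def __iter__(self) -> Iterator[FixationEvent]:
        return iter(self.events)

    def __len__(self) -> int:
        return len(self.events)

    def __eq__(self, other) -> bool:
        return isinstance(other, FixationStream) and self.events == other.events

    def total_duration_ms(self) -> int:
        return sum(e.duration_ms for e in self.events)

    def sorted_by_time(self) -> "FixationStream":
        return FixationStream(sorted(self.events, key=lambda e: e.t_start))


@dataclass(frozen=True)
class ROI:
    """Circular area of interest for one joint site."""

    site_id: str
    cx: float
    cy: float
    radius: float

    def contains(self, x: float, y: float) -> bool:
        # closed disc: boundary points belong to the ROI
        return math.hypot(x - self.cx, y - self.cy) <= self.radius


@dataclass
class ROILayout:
    """All joint ROIs of one radiograph canvas."""

    rois: list[ROI] = field(default_factory=list)

    def __post_init__(self):
        ids = [r.site_id for r in self.rois]
        if len(ids) != len(set(ids)):
            raise ValueError("duplicate site_id in ROI layout")
        if any(r.radius <= 0 for r in self.rois):
            raise ValueError("ROI radii must be positive")

    def __iter__(self) -> Iterator[ROI]:
        return iter(self.rois)

    def __len__(self) -> int:
        return len(self.rois)

    def roi(self, site_id: str) -> ROI:
        for r in self.rois:
            if r.site_id == site_id:
                return r
        raise KeyError(site_id)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(
            json.dumps(
                [
                    {"site_id": r.site_id, "cx": r.cx, "cy": r.cy, "radius": r.radius}
                    for r in self.rois
                ],
                ensure_ascii=False,
                indent=1,
            ),
            encoding="utf-8",
        )

    @classmethod
    def from_json(cls, path: str | Path) -> "ROILayout":
        data = json.loads(Path(path).read_text(encoding="utf-8"))
        return cls(rois=[ROI(d["site_id"], d["cx"], d["cy"], d["radius"]) for d in data])


def _format_coord(v: float) -> str:
    # integers print without a trailing ".0" so exports stay tidy
    return str(int(v)) if float(v).is_integer() else repr(float(v))


def write_fixation_export(stream: FixationStream, path: str | Path) -> None:
    """Write the TSV fixation dialect; inverse of :func:`read_fixation_export`."""
    lines = ["\t".join(EXPORT_HEADER)]
    for e in stream:
        lines.append(
            f"{e.t_start}\t{_format_coord(e.x)}\t{_format_coord(e.y)}\t{e.duration_ms}"
        )
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


class FixationParseError(ValueError):
    """Malformed fixation export; the message names the offending row."""


def read_fixation_export(path: str | Path) -> FixationStream:
    """Parse a TSV fixation export into a time-ordered stream.

    Raises :class:`FixationParseError` naming the 1-based row number for
    missing columns, non-numeric fields, or non-positive durations.
    """
    text = Path(path).read_text(encoding="utf-8")
    lines = [ln for ln in text.splitlines() if ln.strip() != ""]
    if not lines:
        raise FixationParseError(f"{path}: empty file (missing header)")
    header = tuple(lines[0].rstrip("\n").split("\t"))
    if header != EXPORT_HEADER:
        raise FixationParseError(
            f"{path}: row 1: expected header {EXPORT_HEADER}, got {header}"
        )
    events: list[FixationEvent] = []
    for i, ln in enumerate(lines[1:], start=2):
        parts = ln.split("\t")
        if len(parts) != 4:
            raise FixationParseError(f"{path}: row {i}: expected 4 columns, got {len(parts)}")
        try:
            t_start = int(parts[0])
            x = float(parts[1])
            y = float(parts[2])
            duration = int(parts[3])
        except ValueError as exc:
            raise FixationParseError(f"{path}: row {i}: non-numeric field ({exc})") from None
        if duration <= 0:
            raise FixationParseError(f"{path}: row {i}: duration_ms must be > 0, got {duration}")
        events.append(FixationEvent(t_start=t_start, x=x, y=y, duration_ms=duration))
    events.sort(key=lambda e: e.t_start)
    return FixationStream(events=events)
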