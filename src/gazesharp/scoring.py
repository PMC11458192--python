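"""Fixation-duration to mvdH Sharp score conversion.

The reading protocol trains the reader, with a metronome, to dwell 2 s per
Sharp point on a lesion, on top of roughly 1 s spent glancing at any joint,
pathological or not.  The per-joint total fixation duration therefore encodes
the score linearly and the conversion is

    raw = max(0, total_ms / 1000 / 2 - 0.5)

i.e. milliseconds to seconds, halved (2 s per point), minus the half-point
contributed by the 1 s background dwell.  Raw points are rounded half-up to
an integer and clipped to the site's cap, then binned into the ordinal
classes 0..5 and ">=6" used for agreement analysis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping

from .atlas import Atlas, JointSite, Lesion, score_cap

#: Ordered ordinal class labels used throughout agreement analysis.
CLASS_BINS: tuple[str, ...] = ("0", "1", "2", "3", "4", "5", "≥6")


@dataclass(frozen=True)
class JointScore:
    """Eye-tracking Sharp score of one joint for one lesion type."""

    site_id: str
    lesion: Lesion
    total_fixation_ms: float
    raw_score: float
    score: int
    class_bin: str


def fixation_to_raw_score(total_fixation_ms: float) -> float:
    """Continuous Sharp points from a per-joint total fixation duration.

    ``max(0, ms/1000/2 - 0.5)``: 1000 ms (the background dwell on a normal
    joint) maps to 0 points and each further 2000 ms adds one point.
    """
    if total_fixation_ms < 0:
        raise ValueError(f"negative fixation duration: {total_fixation_ms}")
    return max(0.0, total_fixation_ms / 1000.0 / 2.0 - 0.5)


def round_and_clip(raw: float, cap: int) -> int:
    """Nearest integer, ties rounding up, clipped to [0, cap]."""
    if raw < 0:
        raise ValueError(f"negative raw score: {raw}")
    if cap < 1:
        raise ValueError(f"cap must be >= 1, got {cap}")
    return min(int(math.floor(raw + 0.5)), cap)


def class_bin(score: int) -> str:
    """Ordinal class of an integer score: identity for 0-5, '≥6' above."""
    if score < 0:
        raise ValueError(f"negative score: {score}")
    return CLASS_BINS[score] if score <= 5 else CLASS_BINS[6]


def score_site(site: JointSite, lesion: Lesion, total_fixation_ms: float) -> JointScore:
    raw = fixation_to_raw_score(total_fixation_ms)
    rounded = round_and_clip(raw, score_cap(site, lesion))
    return JointScore(
        site_id=site.site_id,
        lesion=lesion,
        total_fixation_ms=total_fixation_ms,
        raw_score=raw,
        score=rounded,
        class_bin=class_bin(rounded),
    )


def score_reading(
    summaries: Iterable,
    atlas: Atlas,
    lesion: Lesion | str,
) -> list[JointScore]:
    """Score every analyzable site of one radiograph reading.

    ``summaries`` are per-site fixation aggregates (``site_id``,
    ``total_fixation_ms``, ``analyzable`` attributes, as produced by
    :func:`gazesharp.processing.assign_fixations`).  Sites flagged
    non-analyzable are omitted; a lesion site absent from the summaries is an
    error naming the site.
    """
    lesion = Lesion(lesion)
    by_site: Mapping[str, object] = {s.site_id: s for s in summaries}
    out: list[JointScore] = []
    for site in atlas:
        if lesion not in site.lesions:
            continue
        summ = by_site.get(site.site_id)
        if summ is None:
            raise ValueError(f"no fixation summary for site {site.site_id!r}")
        if not summ.analyzable:
            continue
        out.append(score_site(site, lesion, summ.total_fixation_ms))
    return out
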