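"""Fixation-to-joint assignment and per-joint dwell-time aggregation.

A fixation whose gaze point falls inside exactly one joint ROI contributes
its duration to that joint.  A fixation falling inside two or more ROIs is
ambiguous — the tracker cannot tell which of two close pathological joints
was being graded — and permanently flags *all* those joints non-analyzable
for this reading; such joints are excluded from scoring and agreement
(mirroring the study's exclusion of joints whose time could not be measured).
Fixations outside every ROI are background and are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .events import FixationStream, ROILayout

# re-exported here because parsing exports is this stage's entry point
from .events import FixationParseError, read_fixation_export  # noqa: F401


@dataclass
class SiteFixationSummary:
    """Aggregated fixation time on one joint in one reading."""

    site_id: str
    total_fixation_ms: int = 0
    n_fixations: int = 0
    analyzable: bool = True


def assign_fixations(stream: FixationStream, layout: ROILayout) -> list[SiteFixationSummary]:
    """Assign each fixation of ``stream`` to the joint ROIs of ``layout``.

    Every layout site appears exactly once in the output, in layout order,
    with zero totals when nothing was assigned.  The non-analyzability flag
    is sticky for the whole reading.
    """
    if len(layout) == 0:
        raise ValueError("ROI layout is empty")
    summaries = {r.site_id: SiteFixationSummary(site_id=r.site_id) for r in layout}
    for ev in stream:
        hits = [r.site_id for r in layout if r.contains(ev.x, ev.y)]
        if not hits:
            continue  # background fixation
        for sid in hits:
            s = summaries[sid]
            s.total_fixation_ms += ev.duration_ms
            s.n_fixations += 1
        if len(hits) >= 2:
            for sid in hits:
                summaries[sid].analyzable = False
    return list(summaries.values())


def summarize_durations(summaries: list[SiteFixationSummary]) -> pd.DataFrame:
    """Tabulate per-site totals: one row per site, layout order preserved."""
    return pd.DataFrame(
        {
            "site_id": [s.site_id for s in summaries],
            "total_fixation_ms": [s.total_fixation_ms for s in summaries],
            "n_fixations": [s.n_fixations for s in summaries],
            "analyzable": [s.analyzable for s in summaries],
        }
    )


def process_export(export_path, layout: ROILayout) -> list[SiteFixationSummary]:
    """Convenience: parse a fixation export and assign it to ``layout``."""
    return assign_fixations(read_fixation_export(export_path), layout)
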