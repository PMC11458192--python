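"""End-to-end orchestration: streams -> scores -> agreement, study-style.

The study design this mirrors: each patient's radiograph canvas is read
twice per lesion type by the eye-tracking reader; the reference score is a
single conventional reading.  Replicate eye-tracking scores are averaged per
joint before agreement analysis (analyses are based on average values), and
a joint excluded as non-analyzable in any replicate is excluded from
agreement entirely.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import pandas as pd

from .atlas import Atlas, Lesion, build_default_atlas
from .agreement import (
    ContingencyTable,
    IccResult,
    KappaResult,
    build_contingency,
    cohen_kappa,
    dichotomize,
    icc,
)
from .events import FixationStream, ROILayout
from .processing import assign_fixations
from .scoring import CLASS_BINS, class_bin, round_and_clip, score_reading

SCORE_COLUMNS = [
    "patient",
    "radiograph",
    "site_id",
    "lesion",
    "replicate",
    "total_fixation_ms",
    "raw_score",
    "score",
    "class_bin",
]


def score_streams(
    streams: Mapping[tuple[int, str, int], FixationStream],
    layout: ROILayout,
    atlas: Atlas | None = None,
) -> pd.DataFrame:
    """Process and score every reading; one row per analyzable joint.

    ``streams`` maps (patient, lesion, replicate) to a fixation stream, as
    produced by :func:`gazesharp.simulate.simulate_study`.
    """
    atlas = atlas or build_default_atlas()
    rows = []
    for (patient, lesion, replicate), stream in sorted(streams.items()):
        summaries = assign_fixations(stream, layout)
        for js in score_reading(summaries, atlas, lesion):
            rows.append(
                (
                    patient,
                    f"p{patient:03d}",
                    js.site_id,
                    js.lesion.value,
                    replicate,
                    js.total_fixation_ms,
                    js.raw_score,
                    js.score,
                    js.class_bin,
                )
            )
    return pd.DataFrame(rows, columns=SCORE_COLUMNS)


def consensus_scores(score_df: pd.DataFrame) -> pd.DataFrame:
    """Average replicate scores per joint; keep joints analyzable in all replicates.

    The replicate mean is rounded half-up back to an integer score and
    re-binned, giving one eye-tracking score per (patient, site, lesion).
    """
    if score_df.empty:
        return pd.DataFrame(columns=["patient", "site_id", "lesion", "score", "class_bin"])
    n_reps = score_df["replicate"].nunique()
    g = score_df.groupby(["patient", "site_id", "lesion"], as_index=False).agg(
        mean_score=("score", "mean"), n=("score", "size")
    )
    g = g[g["n"] == n_reps].copy()
    # caps were applied per replicate at scoring time; the replicate mean
    # cannot exceed them, so rounding needs no further clip
    g["score"] = g["mean_score"].map(lambda m: round_and_clip(m, cap=10**6))
    g["class_bin"] = g["score"].map(class_bin)
    return g[["patient", "site_id", "lesion", "score", "class_bin"]]


def truth_with_classes(truth: pd.DataFrame) -> pd.DataFrame:
    """Reference score table with its ordinal class column."""
    out = truth.rename(columns={"true_score": "score"}).copy()
    out["class_bin"] = out["score"].map(class_bin)
    return out


def agreement_tables(
    eye: pd.DataFrame, ref: pd.DataFrame, lesion: Lesion | str
) -> ContingencyTable:
    """Contingency table of eye-tracking vs reference classes for one lesion."""
    lesion = Lesion(lesion).value
    e = eye[eye["lesion"] == lesion]
    r = ref[ref["lesion"] == lesion]
    merged = e.merge(r, on=["patient", "site_id", "lesion"], suffixes=("_eye", "_ref"))
    pairs = list(zip(merged["class_bin_eye"].astype(str), merged["class_bin_ref"].astype(str)))
    return build_contingency(pairs, bins=CLASS_BINS)


def agreement_report(
    eye: pd.DataFrame, ref: pd.DataFrame, lesion: Lesion | str
) -> dict:
    """Class-level and dichotomized kappa for one lesion, as plain dicts."""
    table = agreement_tables(eye, ref, lesion)
    by_class: KappaResult = cohen_kappa(table)
    yes_no: KappaResult = cohen_kappa(dichotomize(table))
    return {
        "lesion": Lesion(lesion).value,
        "n_joints": table.n,
        "kappa_by_class": by_class.to_dict(),
        "kappa_dichotomized": yes_no.to_dict(),
    }


def replicate_icc(score_df: pd.DataFrame, lesion: Lesion | str) -> IccResult:
    """Intra-reader ICC(2,1) across replicate readings for one lesion."""
    lesion = Lesion(lesion).value
    sub = score_df[score_df["lesion"] == lesion]
    wide = sub.pivot_table(
        index=["patient", "site_id"], columns="replicate", values="score"
    )
    return icc(wide.to_numpy())
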