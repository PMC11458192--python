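#!/usr/bin/env python
"""Score every simulated reading: fixations -> joints -> Sharp points.

Parses the fixation exports written by 01_simulate_study.py, assigns each
fixation to a joint ROI, applies the non-analyzability rule for ambiguous
fixations, converts per-joint dwell time to mvdH Sharp scores, and writes
per-replicate scores plus the replicate-averaged consensus table.
"""

from pathlib import Path

from gazesharp import study
from gazesharp.atlas import build_default_atlas
from gazesharp.events import ROILayout, read_fixation_export
from gazesharp.simulate import parse_export_filename

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"


def main() -> None:
    layout = ROILayout.from_json(STUDY / "layout.json")
    atlas = build_default_atlas()
    streams = {}
    for p in sorted(STUDY.glob("patient*.tsv")):
        streams[parse_export_filename(p.name)] = read_fixation_export(p)

    score_df = study.score_streams(streams, layout, atlas)
    consensus = study.consensus_scores(score_df)
    score_df.to_csv(STUDY / "scores.csv", index=False, encoding="utf-8")
    consensus.to_csv(STUDY / "scores_consensus.csv", index=False, encoding="utf-8")

    n_readings = len(streams)
    n_scored = len(score_df)
    n_expected = sum(
        44 if lesion == "erosion" else 42 for (_, lesion, _) in streams
    )
    print(f"scored {n_readings} readings: {n_scored} joint scores "
          f"({n_expected - n_scored} joints excluded as non-analyzable)")
    print(f"  consensus table: {len(consensus)} joints -> {STUDY / 'scores_consensus.csv'}")


if __name__ == "__main__":
    main()
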