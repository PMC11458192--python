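#!/usr/bin/env python
"""Generate the synthetic eye-tracking study.

Emulates the study design: 10 patients, each patient's hand/foot joints laid
out as ROIs on one radiograph canvas, read twice per lesion type (erosion,
JSN) by a metronome-trained synthetic reader.  Writes the ground-truth score
table, the ROI layout and 40 fixation exports (10 patients x 2 lesions x 2
replicates) under scratch/study/.
"""

import sys
from pathlib import Path

from gazesharp.atlas import build_default_atlas
from gazesharp.events import write_fixation_export
from gazesharp.simulate import SimConfig, export_filename, simulate_study

OUT = Path(__file__).resolve().parents[1] / "scratch" / "study"


def main(seed: int = 1) -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    config = SimConfig(n_patients=10, seed=seed)
    atlas = build_default_atlas()
    truth, layout, streams = simulate_study(config, atlas)

    atlas.to_json(OUT / "atlas.json")
    layout.to_json(OUT / "layout.json")
    truth.to_csv(OUT / "truth.csv", index=False, encoding="utf-8")
    for (patient, lesion, rep), stream in sorted(streams.items()):
        write_fixation_export(stream, OUT / export_filename(patient, lesion, rep))

    n_patho = int((truth["true_score"] > 0).sum())
    print(f"simulated {config.n_patients} patients, seed {seed}")
    print(f"  {len(truth)} true joint scores ({n_patho} pathological)")
    print(f"  {len(streams)} fixation exports -> {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 1)
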