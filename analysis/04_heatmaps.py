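#!/usr/bin/env python
"""Render visualizations for one synthetic reading.

Takes patient 0's first erosion reading from the simulated study and writes,
under scratch/figures/: the duration-weighted Gaussian heatmap (PNG + raw
grid dump), the ordered gaze plot, and the per-joint severity overlay
(green < 1 point, yellow = 1, orange/red >= 2, score printed in each ROI).
"""

from pathlib import Path

from gazesharp import study
from gazesharp.atlas import build_default_atlas
from gazesharp.events import ROILayout, read_fixation_export
from gazesharp.heatmap import (
    render_heatmap,
    render_score_overlay,
    save_gaze_plot_png,
    save_heatmap_png,
)
from gazesharp.processing import assign_fixations
from gazesharp.scoring import score_reading

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
FIGS = ROOT / "scratch" / "figures"

CANVAS_W, CANVAS_H = 1400, 1000


def main() -> None:
    FIGS.mkdir(parents=True, exist_ok=True)
    export = STUDY / "patient000_erosion_rep0.tsv"
    stream = read_fixation_export(export)
    layout = ROILayout.from_json(STUDY / "layout.json")
    atlas = build_default_atlas()

    grid = render_heatmap(stream, CANVAS_W, CANVAS_H, kernel_sigma=15.0)
    save_heatmap_png(grid, FIGS / "heatmap_p0_erosion.png")
    grid.save_txt(FIGS / "heatmap_p0_erosion.txt")
    save_gaze_plot_png(stream, CANVAS_W, CANVAS_H, FIGS / "gazeplot_p0_erosion.png")

    scores = score_reading(assign_fixations(stream, layout), atlas, "erosion")
    img = render_score_overlay(scores, layout, CANVAS_W, CANVAS_H)
    img.save(FIGS / "overlay_p0_erosion.png")

    total_s = stream.total_duration_ms() / 1000.0
    n_patho = sum(1 for s in scores if s.score > 0)
    print(f"rendered reading {export.name}: {len(stream)} fixations, "
          f"{total_s:.1f} s total dwell")
    print(f"  {len(scores)} joints scored, {n_patho} with at least one point")
    print(f"  figures -> {FIGS}")


if __name__ == "__main__":
    main()
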