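"""Fixation heatmaps, ordered gaze plots, and severity colour overlays.

Severity colours follow the three-class rule used to read the maps: green
for a Sharp score below 1, yellow for exactly 1, orange-to-red for 2 and
above.  Heatmaps deposit each fixation's duration at its gaze point and
smooth with an isotropic Gaussian kernel; gaze plots render fixations as
temporally ordered circles whose diameter is proportional to duration.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from pathlib import Path

import numpy as np
from PIL import Image, ImageDraw
from scipy.ndimage import gaussian_filter

from .events import FixationStream, ROILayout

#: Gaze-plot circle diameter per millisecond of fixation (px/ms): a 2 s
#: fixation (one Sharp point) renders as a 100 px circle.
DIAMETER_PX_PER_MS = 0.05

#: Default Gaussian kernel scale for heatmaps, in pixels.
DEFAULT_SIGMA_PX = 15.0


class ColorClass(str, Enum):
    GREEN = "green"
    YELLOW = "yellow"
    ORANGE_RED = "orange_red"


_CLASS_RGB = {
    ColorClass.GREEN: (46, 204, 64),
    ColorClass.YELLOW: (255, 220, 0),
    ColorClass.ORANGE_RED: (255, 65, 54),
}


def color_class(score: int) -> ColorClass:
    """Severity colour of an integer Sharp score (green <1, yellow =1, orange/red >=2)."""
    if score < 0:
        raise ValueError(f"negative score: {score}")
    if score < 1:
        return ColorClass.GREEN
    if score == 1:
        return ColorClass.YELLOW
    return ColorClass.ORANGE_RED


@dataclass
class IntensityGrid:
    """Duration-weighted gaze intensity over the canvas.

    ``raw`` holds the unnormalized mass (total fixation milliseconds spread
    by the kernel, up to boundary truncation); ``values`` is max-normalized
    to 1 for display, or all zeros for an empty stream.
    """

    width: int
    height: int
    raw: np.ndarray  # shape (height, width)

    @property
    def values(self) -> np.ndarray:
        m = self.raw.max()
        return self.raw / m if m > 0 else self.raw.copy()

    def save_txt(self, path: str | Path) -> None:
        np.savetxt(path, self.raw, fmt="%.6g")


def render_heatmap(
    stream: FixationStream,
    width: int,
    height: int,
    kernel_sigma: float = DEFAULT_SIGMA_PX,
) -> IntensityGrid:
    """Gaussian-kernel heatmap of fixation durations on a width x height grid."""
    if width <= 0 or height <= 0:
        raise ValueError("grid dimensions must be positive")
    if kernel_sigma <= 0:
        raise ValueError("kernel_sigma must be positive")
    grid = np.zeros((height, width), dtype=float)
    for ev in stream:
        col = min(max(int(round(ev.x)), 0), width - 1)
        row = min(max(int(round(ev.y)), 0), height - 1)
        grid[row, col] += ev.duration_ms
    if grid.any():
        grid = gaussian_filter(grid, sigma=kernel_sigma, mode="constant")
    return IntensityGrid(width=width, height=height, raw=grid)


def save_heatmap_png(grid: IntensityGrid, path: str | Path, cmap: str = "turbo") -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(grid.width / 100, grid.height / 100), dpi=100)
    ax.imshow(grid.values, cmap=cmap, origin="upper", vmin=0.0, vmax=1.0)
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def render_gaze_plot(stream: FixationStream) -> list[tuple[int, float, float, float]]:
    """Fixations as ordered circles: (order_index, x, y, diameter_px).

    Circles are sorted by fixation start time; diameter is
    ``DIAMETER_PX_PER_MS * duration_ms``.
    """
    ordered = stream.sorted_by_time()
    return [
        (i, ev.x, ev.y, DIAMETER_PX_PER_MS * ev.duration_ms)
        for i, ev in enumerate(ordered)
    ]


def save_gaze_plot_png(
    stream: FixationStream, width: int, height: int, path: str | Path
) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    circles = render_gaze_plot(stream)
    fig, ax = plt.subplots(figsize=(width / 100, height / 100), dpi=100)
    for i, x, y, d in circles:
        ax.add_patch(plt.Circle((x, y), d / 2, fill=False, color="tab:blue", alpha=0.6))
        ax.annotate(str(i + 1), (x, y), ha="center", va="center", fontsize=6)
    ax.set_xlim(0, width)
    ax.set_ylim(height, 0)
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, bbox_inches="tight", pad_inches=0)
    plt.close(fig)


def render_score_overlay(
    scores,
    layout: ROILayout,
    canvas_w: int,
    canvas_h: int,
) -> Image.Image:
    """Severity overlay: each scored site's ROI filled with its class colour
    and annotated with its integer score.

    ``scores`` is an iterable of objects with ``site_id`` and ``score``
    attributes (:class:`gazesharp.scoring.JointScore`).  A score whose site
    is missing from ``layout`` is an error.
    """
    img = Image.new("RGB", (canvas_w, canvas_h), (20, 20, 20))
    draw = ImageDraw.Draw(img)
    for sc in scores:
        try:
            roi = layout.roi(sc.site_id)
        except KeyError:
            raise ValueError(f"score for unknown site {sc.site_id!r}") from None
        rgb = _CLASS_RGB[color_class(sc.score)]
        bbox = (roi.cx - roi.radius, roi.cy - roi.radius, roi.cx + roi.radius, roi.cy + roi.radius)
        draw.ellipse(bbox, fill=rgb, outline=(255, 255, 255))
        draw.text((roi.cx, roi.cy), str(sc.score), fill=(0, 0, 0), anchor="mm")
    return img


def overlay_rgb(score: int) -> tuple[int, int, int]:
    """RGB used by the overlay for a given score (consistent with color_class)."""
    return _CLASS_RGB[color_class(score)]
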