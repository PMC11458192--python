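"""Synthetic fixation streams with the structure the scoring method assumes.

The generator emulates a metronome-trained reader grading radiographs under
an eye tracker.  Per joint, the reader dwells ``baseline_ms`` (default 1 s,
the background time spent on any joint) plus ``ms_per_point`` (default 2 s)
for every true Sharp point, plus Gaussian duration noise truncated at 1 ms.
True per-joint scores are drawn from a discretized truncated normal whose
latent location is calibrated so the realized mean equals the configured
per-site mean (defaults: the study-population per-joint means), with the
configured SD as latent scale.

Joint crowding is modelled geometrically: the default ROI layout places
anatomically adjacent site pairs 1.5 radii apart, so each centre lies in
exactly one ROI while the pair midpoint lies in both.  With probability
``ambiguity_rate`` per reading, a pair containing at least one pathological
joint is "too close": the pathological member's fixations land at the pair
midpoint, which downstream marks both joints non-analyzable.  Each scored
site belongs to exactly one pair, so the expected non-analyzable fraction of
pathological sites equals ``ambiguity_rate``.

Off-joint background fixations are added along the bottom margin of the
canvas and are discarded by ROI assignment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .atlas import Atlas, JointSite, Lesion, Region, build_default_atlas, score_cap
from .events import ROI, FixationEvent, FixationStream, ROILayout
from .events import write_fixation_export  # noqa: F401  (this stage's writer)

# Study-population per-joint mean +- SD of the Sharp score, by lesion type,
# left and right combined.  Keys are (region, name).
EROSION_SCORE_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("hand", "Radius"): (0.25, 0.64),
    ("hand", "Ulna"): (0.45, 0.89),
    ("hand", "Scaphoïd"): (0.40, 1.05),
    ("hand", "Lunatum"): (0.35, 0.75),
    ("hand", "Trapezium"): (0.30, 0.57),
    ("hand", "M1 base"): (0.35, 0.75),
    ("hand", "MCP1"): (0.25, 0.55),
    ("hand", "MCP2"): (0.90, 1.12),
    ("hand", "MCP3"): (0.80, 1.12),
    ("hand", "MCP4"): (0.30, 0.66),
    ("hand", "MCP5"): (0.10, 0.31),
    ("hand", "IPP1"): (0.15, 0.67),
    ("hand", "IPP2"): (0.45, 0.89),
    ("hand", "IPP3"): (0.50, 0.83),
    ("hand", "IPP4"): (0.30, 0.58),
    ("hand", "IPP5"): (0.30, 0.89),
    ("foot", "IP1 foot"): (0.55, 0.93),
    ("foot", "MTP1"): (0.75, 2.05),
    ("foot", "MTP2"): (0.25, 0.64),
    ("foot", "MTP3"): (1.20, 1.99),
    ("foot", "MTP4"): (1.10, 2.08),
    ("foot", "MTP5"): (1.15, 1.73),
}

JSN_SCORE_TABLE: dict[tuple[str, str], tuple[float, float]] = {
    ("hand", "Scaphoïd-radius"): (0.95, 1.40),
    ("hand", "Scaphoïd-Capitatum"): (0.90, 1.02),
    ("hand", "Scaphoïd-Trapezium"): (0.75, 1.41),
    ("hand", "MCC3"): (0.75, 1.55),
    ("hand", "MCC4"): (0.35, 1.09),
    ("hand", "MCC5"): (0.45, 0.95),
    ("hand", "MCP1"): (0.40, 0.82),
    ("hand", "MCP2"): (1.50, 1.54),
    ("hand", "MCP3"): (1.40, 1.47),
    ("hand", "MCP4"): (0.85, 1.39),
    ("hand", "MCP5"): (0.85, 1.53),
    ("hand", "IPP2"): (0.60, 1.19),
    ("hand", "IPP3"): (0.65, 1.22),
    ("hand", "IPP4"): (0.65, 1.35),
    ("hand", "IPP5"): (0.55, 1.10),
    ("foot", "IP1 foot"): (0.90, 1.25),
    ("foot", "MTP1"): (0.70, 1.49),
    ("foot", "MTP2"): (0.80, 1.54),
    ("foot", "MTP3"): (1.25, 1.80),
    ("foot", "MTP4"): (1.45, 1.73),
    ("foot", "MTP5"): (0.80, 1.32),
}

_LESION_CODE = {Lesion.EROSION: 0, Lesion.JSN: 1}
_SACCADE_GAP_MS = 30


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the synthetic reader.

    Defaults reproduce the study setup: 10 patients, 1 s per-joint baseline,
    2 s per Sharp point, two replicate readings per lesion type, and
    study-population per-joint score means.
    """

    n_patients: int = 10
    baseline_ms: float = 1000.0
    ms_per_point: float = 2000.0
    duration_noise_sd_ms: float = 400.0
    score_means: Mapping[tuple[str, str, str], float] | None = None  # (region, name, lesion) -> mean
    score_sds: Mapping[tuple[str, str, str], float] | None = None
    n_replicates: int = 2
    ambiguity_rate: float = 0.05
    canvas_w: int = 1400
    canvas_h: int = 1000
    roi_radius: float = 18.0
    seed: int = 0

    def __post_init__(self):
        if self.n_patients < 0 or self.n_replicates < 1:
            raise ValueError("n_patients must be >= 0 and n_replicates >= 1")
        if min(self.baseline_ms, self.ms_per_point, self.duration_noise_sd_ms) < 0:
            raise ValueError("durations must be non-negative")
        if not 0.0 <= self.ambiguity_rate <= 1.0:
            raise ValueError("ambiguity_rate must be in [0, 1]")

    def mean_sd_for(self, site: JointSite, lesion: Lesion) -> tuple[float, float]:
        key = (site.region.value, site.name, lesion.value)
        table = EROSION_SCORE_TABLE if lesion is Lesion.EROSION else JSN_SCORE_TABLE
        default = table.get((site.region.value, site.name), (0.0, 0.0))
        mean = default[0] if self.score_means is None else self.score_means.get(key, 0.0)
        sd = default[1] if self.score_sds is None else self.score_sds.get(key, 0.0)
        return mean, sd


# ---------------------------------------------------------------------------
# true-score sampling: discretized truncated normal, mean-calibrated

def _discrete_mean(mu: float, sd: float, cap: int) -> float:
    """E[clip(floor(X + 0.5), 0, cap)] for X ~ N(mu, sd)."""
    ks = np.arange(cap + 1)
    upper = norm.cdf((ks + 0.5 - mu) / sd)
    upper[-1] = 1.0
    lower = np.concatenate(([0.0], upper[:-1]))
    return float(np.sum(ks * (upper - lower)))


def calibrate_latent_mean(target_mean: float, sd: float, cap: int) -> float:
    """Latent normal location whose discretized/clipped mean hits ``target_mean``.

    Truncating a normal at zero inflates its mean, so sampling directly at
    the published mean would bias every joint upward; this inverts the
    discretization so the realized mean is exact.
    """
    if not 0.0 <= target_mean < cap:
        raise ValueError(f"target mean {target_mean} outside [0, cap={cap})")
    lo = -10.0 * sd - 1.0
    hi = cap + 10.0 * sd + 1.0
    return brentq(lambda mu: _discrete_mean(mu, sd, cap) - target_mean, lo, hi, xtol=1e-10)


def _draw_scores(rng: np.random.Generator, n: int, mean: float, sd: float, cap: int) -> np.ndarray:
    if mean == 0.0 or sd == 0.0:
        return np.full(n, int(round(mean)), dtype=int)
    mu = calibrate_latent_mean(mean, sd, cap)
    x = rng.normal(mu, sd, size=n)
    return np.clip(np.floor(x + 0.5).astype(int), 0, cap)


def simulate_true_scores(config: SimConfig, atlas: Atlas | None = None) -> pd.DataFrame:
    """Ground-truth score table: one row per (patient, site, lesion).

    Columns: ``patient, site_id, lesion, true_score``.  Deterministic given
    ``config.seed``.
    """
    atlas = atlas or build_default_atlas()
    rows: list[tuple[int, str, str, int]] = []
    # one substream per (site, lesion) so draws are independent of n_patients'
    # iteration order and of other sites
    for lesion in (Lesion.EROSION, Lesion.JSN):
        for si, site in enumerate(atlas):
            if lesion not in site.lesions:
                continue
            mean, sd = config.mean_sd_for(site, lesion)
            cap = score_cap(site, lesion)
            rng = np.random.default_rng([config.seed, 101, _LESION_CODE[lesion], si])
            scores = _draw_scores(rng, config.n_patients, mean, sd, cap)
            for p in range(config.n_patients):
                rows.append((p, site.site_id, lesion.value, int(scores[p])))
    df = pd.DataFrame(rows, columns=["patient", "site_id", "lesion", "true_score"])
    return df.sort_values(["patient", "lesion", "site_id"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# ROI layout

def site_pairs(site_ids: list[str]) -> list[tuple[str, ...]]:
    """Pair consecutive sites within each (region, side) group.

    Pairs model anatomical adjacency; an odd trailing site forms a singleton
    and can never be ambiguous.
    """
    groups: dict[str, list[str]] = {}
    for sid in site_ids:
        prefix = ":".join(sid.split(":")[:2])
        groups.setdefault(prefix, []).append(sid)
    pairs: list[tuple[str, ...]] = []
    for members in groups.values():
        for i in range(0, len(members) - 1, 2):
            pairs.append((members[i], members[i + 1]))
        if len(members) % 2:
            pairs.append((members[-1],))
    return pairs


def make_default_layout(
    atlas: Atlas | None = None,
    canvas_w: int = 1400,
    canvas_h: int = 1000,
    radius: float = 18.0,
) -> ROILayout:
    """Grid layout of all atlas sites on one synthetic radiograph canvas.

    Pair members sit 1.5 radii apart (ROIs overlap; centres un-shared) and
    distinct pairs sit 6 radii apart.  The bottom margin below the grid is
    kept ROI-free for background fixations.
    """
    atlas = atlas or build_default_atlas()
    pairs = site_pairs([s.site_id for s in atlas])
    pitch = 6.0 * radius
    n_cols = max(1, int((canvas_w - 2 * pitch) // pitch))
    rois: list[ROI] = []
    for k, pair in enumerate(pairs):
        row, col = divmod(k, n_cols)
        cx = pitch + col * pitch
        cy = pitch + row * pitch
        if cy + pitch > canvas_h:
            raise ValueError(
                f"canvas {canvas_w}x{canvas_h} too small for {len(pairs)} ROI pairs "
                f"at radius {radius}"
            )
        if len(pair) == 2:
            rois.append(ROI(pair[0], cx - 0.75 * radius, cy, radius))
            rois.append(ROI(pair[1], cx + 0.75 * radius, cy, radius))
        else:
            rois.append(ROI(pair[0], cx, cy, radius))
    return ROILayout(rois=rois)


# ---------------------------------------------------------------------------
# reading simulation

def _split_duration(total: int, max_chunk_ms: int = 1500) -> list[int]:
    n = max(1, math.ceil(total / max_chunk_ms))
    base, rem = divmod(total, n)
    return [base + (1 if i < rem else 0) for i in range(n)]


def _background_points(layout: ROILayout, config: SimConfig) -> list[tuple[float, float]]:
    pts = []
    y = config.canvas_h - 8.0
    for frac in (0.2, 0.5, 0.8):
        x = frac * config.canvas_w
        if all(math.hypot(x - r.cx, y - r.cy) > r.radius + 1.0 for r in layout):
            pts.append((x, y))
    return pts


def simulate_reading(
    truth: pd.DataFrame,
    layout: ROILayout,
    config: SimConfig,
    lesion: Lesion | str,
    replicate: int,
    patient: int,
) -> FixationStream:
    """One replicate eye-tracking reading of one patient's radiograph canvas.

    Emits, per site scored for ``lesion``, fixations inside the site's ROI
    totalling ``baseline + ms_per_point * true_score + noise`` (noise
    truncated at 1 ms); pathological members of "too close" pairs fixate the
    pair midpoint instead; background fixations land outside every ROI.
    """
    lesion = Lesion(lesion)
    sub = truth[(truth["patient"] == patient) & (truth["lesion"] == lesion.value)]
    true_by_site = dict(zip(sub["site_id"], sub["true_score"]))
    scored = [r for r in layout if r.site_id in true_by_site]
    if not scored and len(sub) > 0:
        raise ValueError("layout and truth table share no sites")
    missing = set(true_by_site) - {r.site_id for r in layout}
    if missing:
        raise ValueError(f"truth table has sites absent from layout: {sorted(missing)[:3]}")

    rng = np.random.default_rng([config.seed, 202, patient, _LESION_CODE[lesion], replicate])

    scored_ids = {r.site_id for r in scored}
    ambiguous: set[str] = set()
    midpoint: dict[str, tuple[float, float]] = {}
    for pair in site_pairs([r.site_id for r in layout]):
        members = [sid for sid in pair if sid in scored_ids]
        pathological = [sid for sid in members if true_by_site[sid] > 0]
        if not pathological:
            continue
        if rng.uniform() < config.ambiguity_rate and len(pair) == 2:
            a, b = layout.roi(pair[0]), layout.roi(pair[1])
            mid = ((a.cx + b.cx) / 2.0, (a.cy + b.cy) / 2.0)
            for sid in pathological:
                ambiguous.add(sid)
                midpoint[sid] = mid

    events: list[FixationEvent] = []
    t = 0
    for roi in scored:
        true = true_by_site[roi.site_id]
        total = config.baseline_ms + config.ms_per_point * true
        if config.duration_noise_sd_ms > 0:
            total += rng.normal(0.0, config.duration_noise_sd_ms)
        total_ms = max(1, int(round(total)))
        if roi.site_id in ambiguous:
            cx, cy = midpoint[roi.site_id]
            jitter_r = 0.2 * roi.radius
        else:
            cx, cy = roi.cx, roi.cy
            jitter_r = 0.25 * roi.radius
        for chunk in _split_duration(total_ms):
            ang = rng.uniform(0.0, 2.0 * math.pi)
            rad = jitter_r * math.sqrt(rng.uniform())
            events.append(
                FixationEvent(
                    t_start=t,
                    x=round(cx + rad * math.cos(ang), 2),
                    y=round(cy + rad * math.sin(ang), 2),
                    duration_ms=chunk,
                )
            )
            t += chunk + _SACCADE_GAP_MS
    for (bx, by) in _background_points(layout, config):
        dur = int(rng.integers(100, 500))
        events.append(FixationEvent(t_start=t, x=bx, y=by, duration_ms=dur))
        t += dur + _SACCADE_GAP_MS
    return FixationStream(events=events)


def simulate_study(
    config: SimConfig, atlas: Atlas | None = None
) -> tuple[pd.DataFrame, ROILayout, dict[tuple[int, str, int], FixationStream]]:
    """Full synthetic study: truth table, layout, and one stream per
    (patient, lesion, replicate)."""
    atlas = atlas or build_default_atlas()
    truth = simulate_true_scores(config, atlas)
    layout = make_default_layout(atlas, config.canvas_w, config.canvas_h, config.roi_radius)
    streams: dict[tuple[int, str, int], FixationStream] = {}
    for p in range(config.n_patients):
        for lesion in (Lesion.EROSION, Lesion.JSN):
            for rep in range(config.n_replicates):
                streams[(p, lesion.value, rep)] = simulate_reading(
                    truth, layout, config, lesion, rep, p
                )
    return truth, layout, streams


def export_filename(patient: int, lesion: Lesion | str, replicate: int) -> str:
    """Canonical fixation-export filename for one reading."""
    return f"patient{patient:03d}_{Lesion(lesion).value}_rep{replicate}.tsv"


def parse_export_filename(name: str) -> tuple[int, str, int]:
    stem = Path(name).stem
    parts = stem.split("_")
    if len(parts) != 3 or not parts[0].startswith("patient") or not parts[2].startswith("rep"):
        raise ValueError(f"unrecognized export filename: {name!r}")
    return int(parts[0][len("patient"):]), Lesion(parts[1]).value, int(parts[2][len("rep"):])
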