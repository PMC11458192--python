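# Methods

## The scoring model

The pipeline assumes a reader whose per-joint gaze dwell time encodes the
modified van der Heijde Sharp (mvdH) score linearly: about 1 s of background
dwell on every joint (normal or not) plus 2 s per Sharp point on a lesion,
enforced during training with a metronome. Scoring therefore inverts the
dwell model:

    raw = max(0, total_ms / 1000 / 2 − 0.5)

Note the protocol's shorthand "1 point per 2 seconds" and this formula
disagree at the margin: under the formula one point corresponds to 3 s of
*total* dwell (2 s lesion + 1 s baseline). The formula is authoritative
here; the clip at zero encodes that sub-baseline dwell can never produce
negative points.

Raw points are rounded to the nearest integer with ties rounded up (integer
scores are what agreement tables use, and no rounding rule accompanies the
published integers, so half-up was fixed as the convention) and clipped to
the site cap: erosion 5 per hand joint and 10 per foot joint, JSN 4
everywhere — the standard mvdH caps; the study reports only observed ranges,
not caps.

## Joint inventory

Per patient: 16 erosion sites per hand (distal radius, ulna, scaphoid,
lunate, trapezium, first metacarpal base, MCP1–5, IPP1–5), 15 JSN sites per
hand (scaphoid–radius, scaphoid–capitate, scaphoid–trapezium, CMC3–5,
MCP1–5, IPP2–5 — the thumb IP is not a JSN site in the mvdH convention), and
6 sites per foot (IP1, MTP1–5) scored for both lesions. That yields 44
erosion and 42 JSN sites per patient, hence 440 erosion joints in a
10-patient study. Enumeration order is fixed (hands before feet, right
before left, anatomical order within a region) so serialized artifacts are
reproducible. The inventory's erosion and JSN totals differ (440 vs 420 over
10 patients); both counts are exposed and no reconciliation is attempted.

## Fixation assignment and non-analyzability

ROIs are closed discs (a boundary point is inside). A fixation inside
exactly one disc adds its duration to that joint; inside none, it is
background and discarded; inside two or more, it is ambiguous and
permanently flags *all* covered joints non-analyzable for that reading. The
flag is joint-level and sticky because exclusion in the source protocol is
joint-level: joints whose time could not be measured are dropped entirely,
not partially. Flagged joints are omitted from score tables, and a joint
missing from either side of an eye-vs-reference comparison is excluded
pairwise before the contingency table is built.

## Synthetic study generator

What it emulates, per reading (one patient canvas, one lesion type, one
replicate):

- **True scores** — integer draws per (patient, site, lesion) from a
  discretized truncated normal. The latent scale is the published per-joint
  SD; the latent location is calibrated numerically (Brent root-finding on
  the exact discretized mean) so the *realized* mean equals the published
  per-joint mean. Plain truncation at zero would inflate every mean (e.g. a
  N(0.90, 1.12) truncated and rounded has mean ≈ 1.03), which the
  calibration removes.
- **Dwell durations** — `baseline_ms + ms_per_point × score` plus additive
  Gaussian noise truncated at 1 ms, split into fixation chunks of ≤ 1.5 s
  with 30 ms saccade gaps.
- **Geometry** — all sites of one patient sit on one synthetic canvas.
  Anatomically adjacent site pairs are placed 1.5 radii apart: each centre
  lies in exactly one ROI, but the pair midpoint lies in both. Distinct
  pairs sit 6 radii apart; a margin strip stays ROI-free for background
  fixations.
- **Ambiguity** — per reading, each pair containing at least one
  pathological joint is "too close" with probability `ambiguity_rate`; the
  pathological members' fixations then land at the pair midpoint, which
  triggers the ≥2-ROI rule downstream. Because every site belongs to exactly
  one pair, the expected non-analyzable fraction of pathological sites
  equals `ambiguity_rate` exactly.
- **Background** — a few 100–500 ms fixations on the ROI-free margin, which
  assignment must discard.

Key parameters (units, default, rationale):

| parameter | default | meaning |
|---|---|---|
| `baseline_ms` | 1000 ms | background dwell per joint; cancels the formula's 0.5-point subtraction |
| `ms_per_point` | 2000 ms | metronome pace per Sharp point |
| `duration_noise_sd_ms` | 400 ms | per-joint timing error of a trained human reader; large enough that replicate readings occasionally disagree by one point (a flip needs ~500 ms of error), small relative to the 2 s pace |
| `ambiguity_rate` | 0.05 | fraction of pathological joints lost as "too close"; the source study lost 24/440 erosion and 44/440 JSN joints |
| `n_replicates` | 2 | readings per lesion type |
| `n_patients` | 10 | study size |
| `roi_radius` | 18 px | AOI disc radius on a 1400×1000 px canvas |

With noise and ambiguity set to zero the pipeline is an exact inverse of the
generator — recovered scores equal the truth joint-for-joint and kappa
against truth is 1.0 — which is the backbone correctness test.

What the generator does **not** model: reader *interpretation* error (seeing
a different lesion grade than the truth), saccade kinematics, pupil/blink
signals, calibration drift, or anatomically realistic joint positions.
Synthetic agreement with truth is therefore an upper bound: passing tests
show the computational pipeline is self-consistent, not that a human
reader's eye-tracking scores would agree with a radiologist at any
particular level. The published agreement statistics are instead recomputed
directly from the packaged study tables.

## Agreement statistics

- **Cohen's kappa** (unweighted) on the ordinal classes 0…5 and ≥6, and on
  the dichotomized table (no damage = class 0 vs any damage). The standard
  error is the Fleiss–Cohen–Everitt asymptotic form (via statsmodels) with a
  1.96·SE interval; the source reports CIs without naming a method. A table
  with all mass in one cell has chance agreement 1 and kappa undefined; this
  is an error, not a NaN.
- **ICC(2,1)** — two-way random effects, absolute agreement, single measure
  (via pingouin) — chosen because the same reader re-reads the same joints
  and absolute reproducibility is the question; no variant is named in the
  source. Perfectly reproduced ratings short-circuit to ICC = 1 (the ANOVA F
  ratios degenerate there).
- The packaged agreement tables transcribe the published body cells only;
  the published "Total" rows repeat the first body row rather than summing
  and are ignored. The erosion body sums to 414 although 416 joints are
  described as analyzable; the two-joint gap is left as-is and is within the
  tolerance used when checking the published kappa. The by-class/dichotomized
  attribution follows the arithmetic-consistent reading of the source (0.82
  and 0.68 by class; 0.97 and 0.95 dichotomized).

## Numerical and design choices

- Rounding is half-up everywhere an integer score is produced (conversion
  and replicate averaging), for consistency.
- Replicate readings are combined by averaging the integer scores per joint
  and re-rounding; a joint non-analyzable in any replicate is dropped.
- Heatmaps deposit each fixation's duration at the nearest grid cell and
  smooth with an isotropic Gaussian (default σ = 15 px, configurable; no
  kernel is prescribed by the source). Pre-normalization mass equals total
  dwell time up to boundary truncation; display grids are max-normalized,
  with the raw grid retained. An empty stream yields an all-zero grid and
  skips normalization.
- Gaze-plot circles are ordered by fixation start time with diameter
  0.05 px/ms (a 2 s fixation → 100 px circle).
- The severity palette's "orange to red" gradient is classified as a single
  class (≥ 2 points); only the three-class rule is normative.
- Seeds: every random draw flows from `SimConfig.seed` through named
  substreams (per site, per reading), so identical configs produce
  byte-identical exports regardless of call order.

## Problem sizes used in tests and drivers

The default study (10 patients, 2 lesions × 2 replicates) is used by the
analysis drivers; tests use 3–8 patients for pipeline checks, 40 patients
for the ambiguity-rate Monte-Carlo, 2000 patients for the score-mean
calibration check (draws only, no streams), and n = 400 joints for ICC
variance-component recovery. These sizes give Monte-Carlo errors comfortably
inside the asserted tolerances while keeping the whole suite fast.

## Known limitations

- The generator's canvas is a schematic grid, not a radiograph; ROI
  positions carry no anatomical meaning.
- Only intra-reader timing noise is modelled, so synthetic eye-vs-truth
  agreement is near-perfect by construction (see above).
- The ambiguity model ties "too close" to fixed pair geometry; real
  crowding varies per film and mostly affects the wrist.
- Dichotomized kappa inherits the instability of near-empty off-diagonal
  cells in small studies; the CI conveys this but no exact method is
  provided.
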