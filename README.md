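# gazesharp

Scoring rheumatoid-arthritis hand and foot radiographs by *watching the
reader's eyes*. A reader trained with a metronome dwells about 2 seconds per
modified van der Heijde Sharp (mvdH) point on each lesion; an eye tracker
records per-joint fixation durations, and those durations are converted back
into Sharp scores:

```
raw points = max(0, total_fixation_ms / 1000 / 2 − 0.5)
```

The half-point subtraction removes the ~1 s background dwell spent on any
joint, pathological or not; raw points are rounded half-up to an integer and
clipped at the joint's cap (erosion: 5 per hand joint, 10 per foot joint;
joint-space narrowing: 4 everywhere).

The package is for researchers evaluating eye tracking as a rapid
radiographic scoring and joint-segmentation aid. It provides:

- **`gazesharp.atlas`** — the mvdH joint inventory (16 erosion / 15 JSN
  sites per hand, 6 sites per foot, both lesion types).
- **`gazesharp.simulate`** — a synthetic study generator: ground-truth
  per-joint scores drawn around published per-joint means, fixation streams
  with `baseline + 2 s × score + noise` dwell per joint, replicate readings,
  and "too close" adjacent-joint ambiguity.
- **`gazesharp.processing`** — fixation-export parsing, fixation→ROI
  assignment, per-joint dwell aggregation, and the non-analyzability rule
  (a fixation inside two overlapping joint ROIs flags both joints for
  exclusion from the whole reading).
- **`gazesharp.scoring`** — the duration→score conversion above, plus the
  ordinal class bins 0…5 and ≥6.
- **`gazesharp.heatmap`** — Gaussian fixation heatmaps, ordered gaze plots,
  and severity overlays (green < 1 point, yellow = 1, orange/red ≥ 2).
- **`gazesharp.agreement`** — contingency tables, unweighted Cohen's kappa
  with asymptotic 95% CI (by class and dichotomized into no-damage vs
  any-damage), and intra-reader ICC(2,1) for replicate readings. The
  published 7×7 agreement tables for erosion and JSN ship as fixtures.

## Worked example

```python
from gazesharp import (SimConfig, simulate_study, build_default_atlas,
                       cohen_kappa, load_table2, dichotomize)
from gazesharp import study

# kappa on the published erosion agreement table (414 joints)
r = cohen_kappa(load_table2("erosion"))
print(f"{r.kappa:.3f} ({r.ci_low:.3f}-{r.ci_high:.3f})")   # 0.828 (0.775-0.881)
print(f"{cohen_kappa(dichotomize(load_table2('erosion'))).kappa:.3f}")  # 0.974

# a synthetic noiseless study round-trips exactly
atlas = build_default_atlas()
cfg = SimConfig(n_patients=4, duration_noise_sd_ms=0.0, ambiguity_rate=0.0, seed=42)
truth, layout, streams = simulate_study(cfg, atlas)
eye = study.consensus_scores(study.score_streams(streams, layout, atlas))
table = study.agreement_tables(eye, study.truth_with_classes(truth), "erosion")
print(cohen_kappa(table).kappa)   # 1.0
```

The same stages are scriptable from the shell (`gazesharp simulate / score /
heatmap / agree`), and `analysis/01…04` run the full synthetic study as a
narrative. Running them in order prints, among other things:

```
published agreement tables (eye tracking vs reference reading):
  erosion  n=414: by class kappa 0.828 (95% CI 0.775-0.881); yes/no kappa 0.974 (95% CI 0.950-0.999)
  jsn      n=396: by class kappa 0.682 (95% CI 0.625-0.739); yes/no kappa 0.949 (95% CI 0.915-0.982)
synthetic study (consensus eye score vs ground truth):
  erosion  n=422: by class kappa 0.976; yes/no kappa 0.978; replicate ICC 0.985
```

By class means the 0…5/≥6 ordinal bins; yes/no means no damage (score 0)
versus any damage. The synthetic study's higher kappas reflect that its only
error sources are dwell-timing noise and ambiguous-joint exclusion, not
reader disagreement about lesions.

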