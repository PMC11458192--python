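#!/usr/bin/env python
"""Agreement analysis: published tables and the synthetic study.

Part 1 recomputes Cohen's kappa (by ordinal class 0..5/>=6, and dichotomized
into no-damage vs any-damage) from the packaged study agreement tables for
erosion and JSN.

Part 2 runs the same machinery on the synthetic study from scripts 01-02:
consensus eye-tracking scores vs the generator's ground truth, plus the
intra-reader ICC(2,1) across the two replicate readings.

Writes results/agreement_published.json and results/agreement_synthetic.json.
"""

import json
from pathlib import Path

import pandas as pd

from gazesharp import study
from gazesharp.agreement import cohen_kappa, dichotomize, load_table2

ROOT = Path(__file__).resolve().parents[1]
STUDY = ROOT / "scratch" / "study"
RESULTS = ROOT / "results"


def fmt(r):
    return f"kappa {r.kappa:.3f} (95% CI {r.ci_low:.3f}-{r.ci_high:.3f})"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)

    published = {}
    print("published agreement tables (eye tracking vs reference reading):")
    for lesion in ("erosion", "jsn"):
        table = load_table2(lesion)
        by_class = cohen_kappa(table)
        yes_no = cohen_kappa(dichotomize(table))
        published[lesion] = {
            "n_joints": table.n,
            "kappa_by_class": by_class.to_dict(),
            "kappa_dichotomized": yes_no.to_dict(),
        }
        print(f"  {lesion:8s} n={table.n}: by class {fmt(by_class)}; "
              f"yes/no {fmt(yes_no)}")
    (RESULTS / "agreement_published.json").write_text(
        json.dumps(published, indent=1), encoding="utf-8"
    )

    synthetic = {}
    scores_path = STUDY / "scores.csv"
    if scores_path.exists():
        score_df = pd.read_csv(scores_path)
        truth = pd.read_csv(STUDY / "truth.csv")
        eye = study.consensus_scores(score_df)
        ref = study.truth_with_classes(truth)
        print("synthetic study (consensus eye score vs ground truth):")
        for lesion in ("erosion", "jsn"):
            rep = study.agreement_report(eye, ref, lesion)
            rep["icc_replicates"] = study.replicate_icc(score_df, lesion).to_dict()
            synthetic[lesion] = rep
            print(f"  {lesion:8s} n={rep['n_joints']}: "
                  f"by class kappa {rep['kappa_by_class']['kappa']:.3f}; "
                  f"yes/no kappa {rep['kappa_dichotomized']['kappa']:.3f}; "
                  f"replicate ICC {rep['icc_replicates']['icc']:.3f}")
        (RESULTS / "agreement_synthetic.json").write_text(
            json.dumps(synthetic, indent=1), encoding="utf-8"
        )
    else:
        print("no synthetic scores found; run 01 and 02 first")


if __name__ == "__main__":
    main()
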