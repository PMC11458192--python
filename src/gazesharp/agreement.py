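"""Agreement between eye-tracking and reference Sharp scores.

Eye-tracking and reference readings of the same joints are crossed into a
square ordinal contingency table over the classes 0..5 and ">=6", from which
unweighted Cohen's kappa is computed with the Fleiss-Cohen-Everitt
asymptotic standard error and a 1.96*SE confidence interval.  Tables can be
dichotomized (no damage = class 0, any damage = class >=1) before the same
computation.  Reproducibility of replicate eye-tracking readings is measured
with the two-way random-effects, absolute-agreement, single-measure ICC
(ICC(2,1)).

The study's published agreement tables for erosion and JSN ship as packaged
fixtures (body cells only) and load via :func:`load_table2`.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.inter_rater import cohens_kappa as _sm_cohens_kappa

from .scoring import CLASS_BINS

DICHOTOMOUS_BINS: tuple[str, str] = ("no", "yes")


@dataclass
class ContingencyTable:
    """Square ordinal table crossing eye-tracking (rows) vs reference (columns)."""

    bins: tuple[str, ...]
    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts, dtype=int)
        k = len(self.bins)
        if self.counts.shape != (k, k):
            raise ValueError(f"counts must be {k}x{k}, got {self.counts.shape}")
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    def to_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.counts, index=list(self.bins), columns=list(self.bins))
        df.to_csv(path, encoding="utf-8")

    @classmethod
    def from_csv(cls, path: str | Path) -> "ContingencyTable":
        df = pd.read_csv(path, index_col=0, encoding="utf-8")
        bins = tuple(str(b) for b in df.columns)
        if tuple(str(b) for b in df.index) != bins:
            raise ValueError(f"{path}: row and column bins differ")
        return cls(bins=bins, counts=df.to_numpy())


def build_contingency(
    pairs: Iterable[tuple[str | int, str | int]],
    bins: Sequence[str] = CLASS_BINS,
) -> ContingencyTable:
    """Cross (eye_class, ref_class) pairs into a ContingencyTable.

    ``counts[i, j]`` counts pairs with eye bin ``bins[i]`` and reference bin
    ``bins[j]``; integer classes are accepted and mapped through ``str``.
    """
    bins = tuple(str(b) for b in bins)
    index = {b: i for i, b in enumerate(bins)}
    counts = np.zeros((len(bins), len(bins)), dtype=int)
    for eye, ref in pairs:
        try:
            counts[index[str(eye)], index[str(ref)]] += 1
        except KeyError as exc:
            raise ValueError(f"unknown bin label {exc.args[0]!r}") from None
    return ContingencyTable(bins=bins, counts=counts)


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    se: float
    ci_low: float
    ci_high: float
    p_o: float
    p_e: float

    def to_dict(self) -> dict:
        return {
            "kappa": self.kappa,
            "se": self.se,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "p_o": self.p_o,
            "p_e": self.p_e,
        }


def cohen_kappa(table: ContingencyTable) -> KappaResult:
    """Unweighted Cohen's kappa with asymptotic SE and 95% CI.

    Raises on an empty table and on the degenerate case where all mass sits
    in a single cell (chance agreement p_e = 1, kappa undefined).
    """
    n = table.n
    if n == 0:
        raise ValueError("contingency table is empty")
    p = table.counts / n
    p_o = float(np.trace(p))
    p_e = float(p.sum(axis=0) @ p.sum(axis=1))
    if p_e >= 1.0 - 1e-12:
        raise ValueError("degenerate table: all mass in one cell (p_e = 1)")
    with np.errstate(invalid="ignore", divide="ignore"):
        res = _sm_cohens_kappa(table.counts, return_results=True)
    kappa = float(res.kappa)
    # var_kappa can round to a tiny negative on near-degenerate tables
    se = float(np.sqrt(max(float(res.var_kappa), 0.0)))
    return KappaResult(
        kappa=kappa,
        se=se,
        ci_low=kappa - 1.96 * se,
        ci_high=kappa + 1.96 * se,
        p_o=p_o,
        p_e=p_e,
    )


def dichotomize(table: ContingencyTable) -> ContingencyTable:
    """Collapse to 2x2: "no" = first bin (score 0), "yes" = all other bins."""
    if table.bins[0] not in ("0", DICHOTOMOUS_BINS[0]):
        raise ValueError(f"first bin must be '0', got {table.bins[0]!r}")
    c = table.counts
    counts = np.array(
        [
            [c[0, 0], c[0, 1:].sum()],
            [c[1:, 0].sum(), c[1:, 1:].sum()],
        ],
        dtype=int,
    )
    return ContingencyTable(bins=DICHOTOMOUS_BINS, counts=counts)


@dataclass(frozen=True)
class IccResult:
    icc: float
    ci_low: float
    ci_high: float

    def to_dict(self) -> dict:
        return {"icc": self.icc, "ci_low": self.ci_low, "ci_high": self.ci_high}


def icc(ratings: np.ndarray | pd.DataFrame) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``ratings`` is an (n_joints, k_replicates) array of scores from the same
    reader re-reading the same joints; rows with missing values are dropped.
    """
    import pingouin as pg

    arr = np.asarray(ratings, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ValueError("ratings must be a 2-D array with >= 2 replicate columns")
    arr = arr[~np.isnan(arr).any(axis=1)]
    if arr.shape[0] < 2:
        raise ValueError("need >= 2 joints with complete replicate ratings")
    n, k = arr.shape
    # perfectly reproduced ratings make the ANOVA F ratios blow up; the ICC
    # limit is exactly 1 when joints differ at all
    row_means = arr.mean(axis=1)
    if np.allclose(arr, row_means[:, None]) and row_means.var() > 0:
        return IccResult(icc=1.0, ci_low=1.0, ci_high=1.0)
    long = pd.DataFrame(
        {
            "target": np.repeat(np.arange(n), k),
            "rater": np.tile(np.arange(k), n),
            "rating": arr.ravel(),
        }
    )
    res = pg.intraclass_corr(data=long, targets="target", raters="rater", ratings="rating")
    # two-way random, absolute agreement, single measure: labelled ICC2 or
    # ICC(A,1) depending on the pingouin version
    mask = res["Type"].isin(["ICC2", "ICC(A,1)"])
    row = res[mask].iloc[0]
    ci_col = "CI95%" if "CI95%" in res.columns else "CI95"
    lo, hi = row[ci_col]
    return IccResult(icc=float(row["ICC"]), ci_low=float(lo), ci_high=float(hi))


def load_table2(lesion: str) -> ContingencyTable:
    """Packaged study agreement table ('erosion' or 'jsn'), body cells only."""
    if lesion not in ("erosion", "jsn"):
        raise ValueError(f"lesion must be 'erosion' or 'jsn', got {lesion!r}")
    ref = resources.files("gazesharp.data") / f"table2_{lesion}.csv"
    with resources.as_file(ref) as path:
        return ContingencyTable.from_csv(path)


def pairwise_classes(
    eye: pd.DataFrame, ref: pd.DataFrame
) -> list[tuple[str, str]]:
    """Join eye-tracking and reference score tables on joint identity.

    Both frames need ``patient, site_id, lesion, class_bin`` columns; only
    joints present in both (i.e. analyzable everywhere) are paired.
    """
    keys = ["patient", "site_id", "lesion"]
    merged = eye.merge(ref, on=keys, suffixes=("_eye", "_ref"))
    return list(zip(merged["class_bin_eye"].astype(str), merged["class_bin_ref"].astype(str)))
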