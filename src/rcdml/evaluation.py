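"""Validation metrics and the workflow's bespoke statistics.

Besides the standard ROC-AUC / confusion-matrix metrics this module houses:

* **Divergence AUC** — the within-drug normalised deviation of one
  (feature-selection x classifier) cell's ROC-AUC from the drug's mean over
  all cells, ``D = (a - m) / m``.  Because each drug's cells are compared to
  their own mean, between-drug variance is removed and cells become
  comparable across drugs; by construction the divergences of a drug sum to
  zero.

* **Conservation index** — a scalar for how often the same features are
  re-selected across the R selection rounds (folds x repeats) of one cell.
  With occurrence counts ``c_i`` over unique features,
  ``CI = (sum c_i^2 / sum c_i) / (R / 2)`` — the count-weighted mean
  occurrence normalised so that identical rounds give CI = 2 and fully
  disjoint rounds give CI = 2/R.  CI is binned low (< 0.5), mid (0.5-1.5),
  high (> 1.5).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ConfusionMatrix",
    "DivergenceTable",
    "ConservationIndex",
    "roc_auc",
    "confusion",
    "divergence_auc",
    "conservation_index",
    "bin_auc_by_conservation",
    "divergence_anova",
]


def roc_auc(scores: Sequence[float] | np.ndarray, labels: Sequence[int] | np.ndarray) -> float:
    """Area under the ROC curve by the rank (Mann-Whitney) formulation.

    Tied scores receive half credit, which makes the value identical to
    trapezoidal integration of the ROC curve over all thresholds.
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    n1 = int((y == 1).sum())
    n0 = int((y == 0).sum())
    if n1 == 0 or n0 == 0:
        raise ValueError("ROC-AUC undefined: only one class present")
    ranks = stats.rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2.0) / (n1 * n0))


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def sensitivity(self) -> float | None:
        d = self.tp + self.fn
        return self.tp / d if d else None

    @property
    def specificity(self) -> float | None:
        d = self.tn + self.fp
        return self.tn / d if d else None

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "threshold": self.threshold,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
        }


def confusion(
    scores: Sequence[float] | np.ndarray,
    labels: Sequence[int] | np.ndarray,
    threshold: float = 0.5,
) -> ConfusionMatrix:
    """Counts under the rule: predicted positive iff score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred = scores >= threshold
    return ConfusionMatrix(
        tp=int(((pred) & (y == 1)).sum()),
        fp=int(((pred) & (y == 0)).sum()),
        tn=int(((~pred) & (y == 0)).sum()),
        fn=int(((~pred) & (y == 1)).sum()),
        threshold=float(threshold),
    )


@dataclass
class DivergenceTable:
    divergence: pd.DataFrame  # inhibitors x cells, D values (NaN where undefined)
    row_mean: pd.Series  # per-inhibitor mean AUC m
    undefined_rows: list[str]


def divergence_auc(auc_table: pd.DataFrame) -> DivergenceTable:
    """Within-drug divergence D = (a - m)/m for an inhibitors x cells AUC grid.

    Missing cells are excluded from the row mean; a row needs at least two
    observed cells; a zero row mean marks the row undefined.
    """
    counts = auc_table.notna().sum(axis=1)
    if (counts < 2).any():
        bad = list(auc_table.index[counts < 2])
        raise ValueError(f"rows with fewer than 2 observed cells: {bad}")
    m = auc_table.mean(axis=1, skipna=True)
    undefined = list(auc_table.index[m == 0])
    div = auc_table.sub(m, axis=0).div(m, axis=0)
    div.loc[undefined] = np.nan
    return DivergenceTable(divergence=div, row_mean=m, undefined_rows=undefined)


CI_BINS = {"low": (-np.inf, 0.5), "mid": (0.5, 1.5), "high": (1.5, np.inf)}


def _ci_bin(ci: float) -> str:
    if ci < 0.5:
        return "low"
    if ci <= 1.5:
        return "mid"
    return "high"


@dataclass
class ConservationIndex:
    counts: dict[str, int]  # feature -> occurrence count over rounds
    rounds: int
    k: int
    ci: float
    bin: str


def conservation_index(selections: Sequence[Iterable[str]]) -> ConservationIndex:
    """CI = (sum c_i^2 / sum c_i) / (R/2) over R selection rounds of size k."""
    sets = [list(s) for s in selections]
    if len(sets) < 2:
        raise ValueError("need at least 2 selection rounds")
    k = len(sets[0])
    if any(len(s) != k for s in sets):
        raise ValueError("selection rounds have unequal sizes")
    if any(len(set(s)) != len(s) for s in sets):
        raise ValueError("a selection round contains duplicate features")
    counts: dict[str, int] = {}
    for s in sets:
        for f in s:
            counts[f] = counts.get(f, 0) + 1
    c = np.array(list(counts.values()), dtype=float)
    R = len(sets)
    ci = float((c @ c) / c.sum() / (R / 2.0))
    return ConservationIndex(counts=counts, rounds=R, k=k, ci=ci, bin=_ci_bin(ci))


def bin_auc_by_conservation(
    cells: pd.DataFrame,
    by: tuple[str, str] = ("strategy", "classifier"),
) -> pd.DataFrame:
    """Per-contrast counts of drugs above/below the median AUC, split by CI bin.

    ``cells`` is tidy with columns [inhibitor, strategy, classifier, auc, ci_bin].
    Within each (strategy, classifier) contrast the median AUC over inhibitors
    defines above/below; counts are reported per conservation bin.
    """
    required = {"inhibitor", "auc", "ci_bin", *by}
    missing = required - set(cells.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for key, grp in cells.groupby(list(by)):
        med = grp["auc"].median()
        for bin_name in ("low", "mid", "high"):
            sub = grp[grp["ci_bin"] == bin_name]
            rows.append(
                {
                    **dict(zip(by, key)),
                    "ci_bin": bin_name,
                    "n": len(sub),
                    "n_above_median": int((sub["auc"] > med).sum()),
                    "n_below_median": int((sub["auc"] < med).sum()),
                    "median_auc": med,
                }
            )
    return pd.DataFrame(rows)


def divergence_anova(div: DivergenceTable, cell_split: str = "cell") -> dict:
    """Convenience one-way ANOVA of divergence scores across cells.

    Thin wrapper over :func:`scipy.stats.f_oneway`; not part of the method
    core.
    """
    groups = [
        div.divergence[c].dropna().to_numpy()
        for c in div.divergence.columns
        if div.divergence[c].notna().sum() >= 2
    ]
    if len(groups) < 2:
        raise ValueError("need at least two cells with >= 2 observations")
    f, p = stats.f_oneway(*groups)
    return {"F": float(f), "p": float(p), "n_groups": len(groups)}
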