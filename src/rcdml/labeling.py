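"""Quantile labelling of a cohort's drug-response AUC vector.

Subjects strictly beyond the upper quantile of the cohort's response
distribution form one class, subjects strictly below the lower quantile the
other, and everything in between is excluded from classification.  Which tail
is called "responder" is controlled explicitly: for ex vivo viability assays a
LOW drug AUC usually means the drug killed the cells (sensitive/responder),
but the opposite convention also appears in the literature, so the direction
is a mandatory, recorded parameter rather than a guess.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = ["Direction", "ResponseLabels", "assign_labels", "label_balance"]

RESPONDER = "responder"
NON_RESPONDER = "non_responder"
EXCLUDED = "excluded"


class Direction(str, Enum):
    """Which tail of the drug-AUC distribution counts as responder."""

    HIGH_AUC_IS_RESPONDER = "high_auc_is_responder"
    LOW_AUC_IS_RESPONDER = "low_auc_is_responder"


@dataclass
class ResponseLabels:
    classes: pd.Series  # sample_id -> {responder, non_responder, excluded}
    low_q: float
    high_q: float
    low_threshold: float
    high_threshold: float
    direction: Direction

    def __post_init__(self) -> None:
        if not (0 < self.low_q < self.high_q < 1):
            raise ValueError("need 0 < low_q < high_q < 1")
        bad = set(self.classes.unique()) - {RESPONDER, NON_RESPONDER, EXCLUDED}
        if bad:
            raise ValueError(f"unknown classes {bad}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.classes.index)

    def labeled_samples(self) -> list[str]:
        keep = self.classes != EXCLUDED
        return list(self.classes.index[keep])

    def binary(self) -> pd.Series:
        """0/1 vector over the non-excluded samples (responder = 1)."""
        keep = self.classes[self.classes != EXCLUDED]
        return (keep == RESPONDER).astype(int)


def assign_labels(
    auc: Sequence[float] | np.ndarray,
    sample_ids: Sequence[str] | None = None,
    low_q: float = 0.25,
    high_q: float = 0.75,
    direction: Direction = Direction.HIGH_AUC_IS_RESPONDER,
    quantile_method: str = "linear",
) -> ResponseLabels:
    """Label each subject by its position in the cohort AUC distribution.

    Quantile thresholds use linear interpolation between order statistics by
    default (``quantile_method`` follows :func:`numpy.quantile`).  Ties at a
    threshold are excluded — the inequalities are strict on both sides.  A
    constant vector labels everything excluded with a warning.
    """
    auc = np.asarray(auc, dtype=float)
    if auc.ndim != 1 or auc.size < 4:
        raise ValueError("need a 1-d response vector with at least 4 values")
    if not np.isfinite(auc).all():
        raise ValueError("response vector contains non-finite values")
    if not (0 < low_q < high_q < 1):
        raise ValueError("need 0 < low_q < high_q < 1")
    direction = Direction(direction)
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(auc.size)]
    if len(sample_ids) != auc.size:
        raise ValueError("sample_ids length mismatch")

    lo = float(np.quantile(auc, low_q, method=quantile_method))
    hi = float(np.quantile(auc, high_q, method=quantile_method))

    if direction is Direction.HIGH_AUC_IS_RESPONDER:
        upper_cls, lower_cls = RESPONDER, NON_RESPONDER
    else:
        upper_cls, lower_cls = NON_RESPONDER, RESPONDER

    classes = np.full(auc.size, EXCLUDED, dtype=object)
    classes[auc > hi] = upper_cls
    classes[auc < lo] = lower_cls
    if auc.max() == auc.min():
        warnings.warn(
            "constant response vector: all samples excluded", stacklevel=2
        )
    return ResponseLabels(
        classes=pd.Series(classes, index=list(sample_ids), name="class"),
        low_q=low_q,
        high_q=high_q,
        low_threshold=lo,
        high_threshold=hi,
        direction=direction,
    )


def label_balance(labels: ResponseLabels) -> tuple[int, int, int]:
    """(n_responder, n_non_responder, n_excluded); sums to the cohort size."""
    c = labels.classes.value_counts()
    return (
        int(c.get(RESPONDER, 0)),
        int(c.get(NON_RESPONDER, 0)),
        int(c.get(EXCLUDED, 0)),
    )
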