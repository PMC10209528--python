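"""ROC-AUC, confusion counts, divergence scores and the conservation index."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from rcdml.evaluation import (
    bin_auc_by_conservation,
    confusion,
    conservation_index,
    divergence_auc,
    roc_auc,
)


# ----------------------------------------------------------------------
# ROC-AUC
# ----------------------------------------------------------------------
def test_perfect_and_inverted_separation():
    scores = np.array([0.1, 0.2, 0.8, 0.9])
    labels = np.array([0, 0, 1, 1])
    assert roc_auc(scores, labels) == 1.0
    assert roc_auc(scores, 1 - labels) == 0.0


def test_label_inversion_symmetry():
    rng = np.random.default_rng(0)
    scores = rng.normal(size=50)
    labels = rng.integers(0, 2, 50)
    while len(np.unique(labels)) < 2:
        labels = rng.integers(0, 2, 50)
    assert roc_auc(scores, labels) == pytest.approx(1.0 - roc_auc(scores, 1 - labels))


def test_rank_formulation_equals_trapezoidal_integration():
    """Dual-algorithm oracle: Mann-Whitney ranks vs trapezoid over thresholds."""
    from sklearn.metrics import roc_curve

    rng = np.random.default_rng(1)
    worst = 0.0
    for _ in range(1000):
        n = rng.integers(4, 40)
        scores = np.round(rng.normal(size=n), rng.integers(0, 3))  # force ties often
        labels = rng.integers(0, 2, n)
        if len(np.unique(labels)) < 2:
            continue
        fpr, tpr, _ = roc_curve(labels, scores)
        trapezoid = float(np.trapezoid(tpr, fpr))
        worst = max(worst, abs(roc_auc(scores, labels) - trapezoid))
    assert worst < 1e-12


def test_single_class_is_error():
    with pytest.raises(ValueError, match="one class"):
        roc_auc([0.1, 0.2], [1, 1])


# ----------------------------------------------------------------------
# confusion
# ----------------------------------------------------------------------
def test_confusion_all_positive_scores_and_labels():
    cm = confusion(np.ones(7), np.ones(7, dtype=int))
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (7, 0, 0, 0)
    assert cm.sensitivity == 1.0
    assert cm.specificity is None  # no negatives: 0/0


def test_confusion_threshold_zero_predicts_everything_positive():
    scores = np.array([0.1, 0.4, 0.9])
    labels = np.array([0, 1, 1])
    cm = confusion(scores, labels, threshold=0.0)
    assert cm.specificity == 0.0
    assert cm.fp == 1 and cm.tn == 0


def test_confusion_matches_brute_force_counting():
    rng = np.random.default_rng(2)
    scores = rng.uniform(size=200)
    labels = rng.integers(0, 2, 200)
    cm = confusion(scores, labels, threshold=0.6)
    tp = fp = tn = fn = 0
    for s, y in zip(scores, labels):
        pred = s >= 0.6
        if pred and y == 1:
            tp += 1
        elif pred and y == 0:
            fp += 1
        elif not pred and y == 0:
            tn += 1
        else:
            fn += 1
    assert (cm.tp, cm.fp, cm.tn, cm.fn) == (tp, fp, tn, fn)
    assert cm.n == 200


# ----------------------------------------------------------------------
# divergence AUC
# ----------------------------------------------------------------------
def test_divergence_worked_row():
    grid = pd.DataFrame({"c1": [0.8], "c2": [0.6]}, index=["drugA"])
    table = divergence_auc(grid)
    assert table.row_mean["drugA"] == pytest.approx(0.7)
    assert table.divergence.loc["drugA", "c1"] == pytest.approx(1 / 7)
    assert table.divergence.loc["drugA", "c2"] == pytest.approx(-1 / 7)


def test_divergence_all_equal_cells_give_zero():
    grid = pd.DataFrame(np.full((3, 4), 0.7), index=list("abc"))
    assert np.allclose(divergence_auc(grid).divergence.to_numpy(), 0.0)


def test_divergence_rows_sum_to_zero_on_random_grids():
    rng = np.random.default_rng(3)
    for _ in range(20):
        grid = pd.DataFrame(
            rng.uniform(0.3, 1.0, size=(24, 9)),
            index=[f"drug{i}" for i in range(24)],
        )
        sums = divergence_auc(grid).divergence.sum(axis=1)
        assert np.abs(sums.to_numpy()).max() < 1e-12


def test_divergence_missing_cells_excluded_from_mean():
    grid = pd.DataFrame({"c1": [0.9], "c2": [np.nan], "c3": [0.6]}, index=["d"])
    table = divergence_auc(grid)
    assert table.row_mean["d"] == pytest.approx(0.75)
    assert np.isnan(table.divergence.loc["d", "c2"])


def test_divergence_requires_two_observed_cells():
    grid = pd.DataFrame({"c1": [0.9], "c2": [np.nan]}, index=["d"])
    with pytest.raises(ValueError, match="fewer than 2"):
        divergence_auc(grid)


# ----------------------------------------------------------------------
# conservation index
# ----------------------------------------------------------------------
def test_ci_identical_rounds_full_conservation():
    sets = [[f"g{i}" for i in range(30)]] * 50
    ci = conservation_index(sets)
    assert ci.ci == pytest.approx(2.0)
    assert ci.bin == "high"


def test_ci_disjoint_rounds_full_uniqueness():
    sets = [[f"g{r}_{i}" for i in range(30)] for r in range(50)]
    ci = conservation_index(sets)
    assert ci.ci == pytest.approx(0.04)
    assert ci.bin == "low"


def test_ci_worked_half_overlap_case():
    a = ["g1", "g2", "g3", "g4"]
    b = ["g1", "g2", "g5", "g6"]
    ci = conservation_index([a, b])
    assert sorted(ci.counts.values()) == [1, 1, 1, 1, 2, 2]
    assert ci.ci == pytest.approx(1.5)
    assert ci.bin == "mid"


def test_ci_swapping_unique_for_shared_never_decreases():
    base = [[f"g{i}" for i in range(5)], ["g0", "g1", "x2", "x3", "x4"]]
    lower = conservation_index(base).ci
    more_shared = [[f"g{i}" for i in range(5)], ["g0", "g1", "g2", "x3", "x4"]]
    assert conservation_index(more_shared).ci >= lower


@settings(derandomize=True, max_examples=25, deadline=None)
@given(st.integers(0, 10_000), st.randoms(use_true_random=False))
def test_ci_invariant_to_round_order_and_renaming(seed, rnd):
    rng = np.random.default_rng(seed)
    pool = [f"g{i}" for i in range(12)]
    sets = [list(rng.choice(pool, size=4, replace=False)) for _ in range(6)]
    base = conservation_index(sets).ci
    shuffled = sets[:]
    rnd.shuffle(shuffled)
    assert conservation_index(shuffled).ci == pytest.approx(base)
    renamed = [[f"XX{p[1:]}" for p in s] for s in sets]
    assert conservation_index(renamed).ci == pytest.approx(base)


def test_ci_rejects_degenerate_inputs():
    with pytest.raises(ValueError, match="at least 2"):
        conservation_index([["a", "b"]])
    with pytest.raises(ValueError, match="unequal"):
        conservation_index([["a", "b"], ["a"]])
    with pytest.raises(ValueError, match="duplicate"):
        conservation_index([["a", "a"], ["a", "b"]])


# ----------------------------------------------------------------------
# binning AUC by conservation
# ----------------------------------------------------------------------
def _tidy_cells(rng, bins):
    rows = []
    for i, b in enumerate(bins):
        rows.append(
            {
                "inhibitor": f"d{i}",
                "strategy": "shap",
                "classifier": "rf",
                "auc": rng.uniform(0.5, 1.0),
                "ci_bin": b,
            }
        )
    return pd.DataFrame(rows)


def test_binned_counts_sum_to_total_cells():
    rng = np.random.default_rng(5)
    cells = _tidy_cells(rng, ["low"] * 6 + ["mid"] * 6 + ["high"] * 12)
    out = bin_auc_by_conservation(cells)
    assert out["n"].sum() == len(cells)
    empty = bin_auc_by_conservation(_tidy_cells(rng, ["high"] * 8))
    assert empty.loc[empty["ci_bin"] == "low", "n"].sum() == 0


def test_high_ci_cells_constructed_with_higher_auc_sit_above_median():
    rng = np.random.default_rng(6)
    cells = _tidy_cells(rng, ["low"] * 12 + ["high"] * 12)
    cells.loc[cells["ci_bin"] == "high", "auc"] += 0.5
    out = bin_auc_by_conservation(cells)
    high = out[out["ci_bin"] == "high"].iloc[0]
    assert high["n_above_median"] > high["n_below_median"]
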