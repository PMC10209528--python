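"""Shared fixtures and independent oracles for the test suite.

The Shapley oracle here enumerates every feature coalition and computes the
tree's path-conditional expectation recursively — exponential-time, entirely
independent of the polynomial path algorithm it is used to check.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from rcdml.dataio import DrugResponseTable, ExpressionMatrix, match_cohort
from rcdml.synthetic import SyntheticSpec, generate_cohort


def tree_conditional_expectation(tree, x: np.ndarray, known: set[int]) -> float:
    """E[tree(x)] with only the features in ``known`` fixed to x's values.

    Unknown features split the walk proportionally to child training cover
    (the path-dependent convention).
    """

    def rec(j: int) -> float:
        if tree.is_leaf(j):
            return float(tree.value[j])
        f = tree.feature[j]
        left, right = tree.children_left[j], tree.children_right[j]
        if f in known:
            return rec(left if tree._goes_left(j, x[f]) else right)
        cj = tree.cover[j] if tree.cover[j] > 0 else 1.0
        return (tree.cover[left] * rec(left) + tree.cover[right] * rec(right)) / cj

    return rec(0)


def brute_force_shapley(ensemble, x: np.ndarray, n_features: int) -> np.ndarray:
    """Exhaustive-coalition Shapley values of an additive tree ensemble."""

    def v(S: set[int]) -> float:
        return sum(
            s * tree_conditional_expectation(t, x, S)
            for s, t in zip(ensemble.scales, ensemble.trees)
        )

    phi = np.zeros(n_features)
    for i in range(n_features):
        rest = [f for f in range(n_features) if f != i]
        for r in range(len(rest) + 1):
            for S in itertools.combinations(rest, r):
                S = set(S)
                w = (
                    math.factorial(len(S))
                    * math.factorial(n_features - len(S) - 1)
                    / math.factorial(n_features)
                )
                phi[i] += w * (v(S | {i}) - v(S))
    return phi


@pytest.fixture(scope="session")
def small_expression() -> ExpressionMatrix:
    genes = ["GA", "GB", "GC"]
    samples = ["s1", "s2"]
    vals = np.array([[1.0, 2.0], [0.5, 0.0], [10.0, 3.5]])
    return ExpressionMatrix(pd.DataFrame(vals, index=genes, columns=samples))


@pytest.fixture(scope="session")
def planted_cohort():
    """Small planted-signal cohort shared by selection/pipeline unit tests."""
    spec = SyntheticSpec(
        n_samples=200, n_genes=400, n_informative=10, effect_size=2.0, seed=123
    )
    expr, resp, truth = generate_cohort(spec)
    cohort = match_cohort(expr, resp, "SYN-1")
    return cohort, truth


@pytest.fixture(scope="session")
def labeled_training_split(planted_cohort):
    """Samples x genes CPM frame and 0/1 labels for the planted cohort tails."""
    from rcdml.labeling import assign_labels

    cohort, truth = planted_cohort
    labels = assign_labels(cohort.response_auc, cohort.sample_ids)
    y = labels.binary()
    cpm = cohort.expression.samples_by_genes().loc[list(y.index)]
    return cpm, y.to_numpy(), truth
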