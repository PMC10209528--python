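"""Exact Shapley attributions for tree ensembles (path-dependent TreeSHAP).

The Shapley value of feature i for a prediction f(x) averages the marginal
change in the model's conditional expectation over all feature coalitions.
Evaluated naively this is exponential in the number of features; for decision
trees the polynomial-time path algorithm computes it exactly by carrying, down
each root-to-leaf path, the permutation weights of every subset size at once
("EXTEND"/"UNWIND" recursion).  The conditional expectation convention is
path-dependent: when a feature is not in the coalition, the walk splits
proportionally to the training cover (node sample weight) of each child —
the convention of the canonical tree-explainer.

Attributions are additive on the margin scale:
``sum_i phi_i(x) = f(x) - E[f]`` with E the cover-weighted expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = ["Tree", "TreeEnsemble", "tree_shap", "mean_abs_attribution"]


@dataclass
class Tree:
    """Array-form binary decision tree.

    ``children_left``/``children_right`` hold child node indices (-1 at a
    leaf).  ``split_rule`` is ``"le"`` (go left when x <= threshold, the
    sklearn convention) or ``"lt"`` (go left when x < threshold, the XGBoost
    convention).  ``cover`` is the training sample weight reaching each node
    (sum of hessians for boosters); it defines the path-dependent expectation.
    ``value`` holds the scalar output at each leaf (internal entries unused).
    """

    children_left: np.ndarray
    children_right: np.ndarray
    feature: np.ndarray
    threshold: np.ndarray
    value: np.ndarray
    cover: np.ndarray
    split_rule: str = "le"

    def __post_init__(self) -> None:
        n = len(self.children_left)
        for name in ("children_right", "feature", "threshold", "value", "cover"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"{name} length != number of nodes")
        if self.split_rule not in ("le", "lt"):
            raise ValueError("split_rule must be 'le' or 'lt'")
        if np.any(self.cover < 0):
            raise ValueError("negative node cover")

    def is_leaf(self, node: int) -> bool:
        return self.children_left[node] < 0

    def _goes_left(self, node: int, xval: float) -> bool:
        t = self.threshold[node]
        return xval <= t if self.split_rule == "le" else xval < t

    def predict_one(self, x: np.ndarray) -> float:
        j = 0
        while not self.is_leaf(j):
            j = (
                self.children_left[j]
                if self._goes_left(j, x[self.feature[j]])
                else self.children_right[j]
            )
        return float(self.value[j])

    def expected_value(self) -> float:
        """Cover-weighted mean leaf value (the model output with no features known)."""

        def rec(j: int) -> float:
            if self.is_leaf(j):
                return float(self.value[j])
            l, r = self.children_left[j], self.children_right[j]
            cj = self.cover[j]
            if cj <= 0:
                return 0.5 * (rec(l) + rec(r))
            return (self.cover[l] * rec(l) + self.cover[r] * rec(r)) / cj

        return rec(0)

    def max_depth(self) -> int:
        def rec(j: int) -> int:
            if self.is_leaf(j):
                return 0
            return 1 + max(rec(self.children_left[j]), rec(self.children_right[j]))

        return rec(0)


@dataclass
class TreeEnsemble:
    """Additive ensemble: margin(x) = sum_t scale_t * tree_t(x)."""

    trees: list[Tree]
    scales: list[float] | None = None
    n_features: int = 0

    def __post_init__(self) -> None:
        if self.scales is None:
            self.scales = [1.0] * len(self.trees)
        if len(self.scales) != len(self.trees):
            raise ValueError("scales length != number of trees")
        if self.n_features <= 0:
            hi = 0
            for t in self.trees:
                internal = t.feature[t.children_left >= 0]
                if internal.size:
                    hi = max(hi, int(internal.max()) + 1)
            self.n_features = hi

    def predict_margin(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=float))
        out = np.zeros(X.shape[0])
        for s, t in zip(self.scales, self.trees):
            out += s * np.array([t.predict_one(x) for x in X])
        return out

    def expected_value(self) -> float:
        return float(sum(s * t.expected_value() for s, t in zip(self.scales, self.trees)))

    # ------------------------------------------------------------------
    # converters
    # ------------------------------------------------------------------
    @classmethod
    def from_sklearn(cls, model) -> "TreeEnsemble":
        """Convert sklearn decision trees / forests / gradient boosting.

        Classifier leaves contribute the class-1 probability; gradient
        boosting trees contribute raw (margin-scale) values times the
        learning rate.
        """
        from sklearn.ensemble import (
            GradientBoostingClassifier,
            GradientBoostingRegressor,
            RandomForestClassifier,
            RandomForestRegressor,
        )
        from sklearn.tree import DecisionTreeClassifier, DecisionTreeRegressor

        def one(est, classifier: bool) -> Tree:
            t = est.tree_
            val = t.value[:, 0, :]
            if classifier:
                if val.shape[1] == 1:
                    leaf_val = val[:, 0]
                else:
                    totals = val.sum(axis=1)
                    totals[totals == 0] = 1.0
                    leaf_val = val[:, -1] / totals
            else:
                leaf_val = val[:, 0]
            return Tree(
                children_left=t.children_left.copy(),
                children_right=t.children_right.copy(),
                feature=t.feature.copy(),
                threshold=t.threshold.copy(),
                value=np.asarray(leaf_val, dtype=float),
                cover=t.weighted_n_node_samples.copy(),
                split_rule="le",
            )

        if isinstance(model, (DecisionTreeClassifier, DecisionTreeRegressor)):
            is_clf = isinstance(model, DecisionTreeClassifier)
            return cls([one(model, is_clf)], [1.0], model.n_features_in_)
        if isinstance(model, (RandomForestClassifier, RandomForestRegressor)):
            is_clf = isinstance(model, RandomForestClassifier)
            n = len(model.estimators_)
            return cls(
                [one(e, is_clf) for e in model.estimators_],
                [1.0 / n] * n,
                model.n_features_in_,
            )
        if isinstance(model, (GradientBoostingClassifier, GradientBoostingRegressor)):
            trees = [one(e, False) for e in model.estimators_[:, 0]]
            return cls(trees, [model.learning_rate] * len(trees), model.n_features_in_)
        raise TypeError(f"unsupported sklearn model {type(model).__name__}")

    @classmethod
    def from_xgboost(cls, model) -> "TreeEnsemble":
        """Convert a fitted XGBoost classifier/regressor via its tree dump.

        Leaf values are margin increments; cover is the per-node hessian sum
        recorded at training time.
        """
        booster = model.get_booster() if hasattr(model, "get_booster") else model
        df = booster.trees_to_dataframe()
        names = booster.feature_names
        if names is not None:
            fmap = {n: i for i, n in enumerate(names)}
        else:
            fmap = None

        def fidx(name: str) -> int:
            if fmap is not None and name in fmap:
                return fmap[name]
            return int(name.lstrip("f"))

        trees: list[Tree] = []
        n_features = getattr(model, "n_features_in_", 0)
        for _, sub in df.groupby("Tree", sort=True):
            sub = sub.sort_values("Node")
            ids = {nid: k for k, nid in enumerate(sub["ID"])}
            n = len(sub)
            cl = np.full(n, -1, dtype=int)
            cr = np.full(n, -1, dtype=int)
            feat = np.full(n, -1, dtype=int)
            thr = np.zeros(n)
            val = np.zeros(n)
            cov = np.zeros(n)
            for k, row in enumerate(sub.itertuples(index=False)):
                cov[k] = row.Cover
                if row.Feature == "Leaf":
                    val[k] = row.Gain
                else:
                    feat[k] = fidx(row.Feature)
                    thr[k] = row.Split
                    cl[k] = ids[row.Yes]
                    cr[k] = ids[row.No]
            trees.append(
                Tree(
                    children_left=cl,
                    children_right=cr,
                    feature=feat,
                    threshold=thr,
                    value=val,
                    cover=cov,
                    split_rule="lt",
                )
            )
        return cls(trees, [1.0] * len(trees), n_features)


# ----------------------------------------------------------------------
# the path algorithm
# ----------------------------------------------------------------------
def _shap_one_tree(tree: Tree, x: np.ndarray, phi: np.ndarray, scale: float) -> None:
    children_left = tree.children_left
    children_right = tree.children_right
    feature = tree.feature
    value = tree.value
    cover = tree.cover

    def recurse(
        j: int,
        d: list[int],
        z: list[float],
        o: list[float],
        w: list[float],
        pz: float,
        po: float,
        pi: int,
    ) -> None:
        # EXTEND: add one path element and update the permutation weights
        l = len(w)
        d = d + [pi]
        z = z + [pz]
        o = o + [po]
        w = w + [1.0 if l == 0 else 0.0]
        for i in range(l - 1, -1, -1):
            w[i + 1] += po * w[i] * (i + 1) / (l + 1)
            w[i] = pz * w[i] * (l - i) / (l + 1)

        left = children_left[j]
        if left < 0:
            ud = len(d) - 1
            leaf = value[j] * scale
            for i in range(1, ud + 1):
                # sum of weights with element i unwound
                one_f, zero_f = o[i], z[i]
                total = 0.0
                nxt = w[ud]
                if one_f != 0:
                    for k in range(ud - 1, -1, -1):
                        tmp = nxt / ((k + 1) * one_f)
                        total += tmp
                        nxt = w[k] - tmp * zero_f * (ud - k)
                else:
                    for k in range(ud - 1, -1, -1):
                        total += w[k] / (zero_f * (ud - k))
                phi[d[i]] += total * (ud + 1) * (one_f - zero_f) * leaf
            return

        right = children_right[j]
        f = feature[j]
        if tree._goes_left(j, x[f]):
            hot, cold = left, right
        else:
            hot, cold = right, left
        cj = cover[j] if cover[j] > 0 else 1.0
        hot_frac = cover[hot] / cj
        cold_frac = cover[cold] / cj

        iz, io = 1.0, 1.0
        ud = len(d) - 1
        k_found = -1
        for k in range(1, ud + 1):
            if d[k] == f:
                k_found = k
                break
        if k_found >= 0:
            # UNWIND the previous occurrence of this feature
            iz, io = z[k_found], o[k_found]
            nxt = w[ud]
            for i in range(ud - 1, -1, -1):
                if io != 0:
                    tmp = w[i]
                    w[i] = nxt * (ud + 1) / ((i + 1) * io)
                    nxt = tmp - w[i] * iz * (ud - i) / (ud + 1)
                else:
                    w[i] = w[i] * (ud + 1) / (iz * (ud - i))
            d = d[:k_found] + d[k_found + 1 :]
            z = z[:k_found] + z[k_found + 1 :]
            o = o[:k_found] + o[k_found + 1 :]
            w = w[:ud]

        recurse(hot, d[:], z[:], o[:], w[:], iz * hot_frac, io, f)
        recurse(cold, d[:], z[:], o[:], w[:], iz * cold_frac, 0.0, f)

    recurse(0, [], [], [], [], 1.0, 1.0, -1)


def tree_shap(ensemble: TreeEnsemble, X: np.ndarray) -> np.ndarray:
    """Per-sample, per-feature Shapley attributions (n_samples x n_features)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_features = max(ensemble.n_features, X.shape[1])
    phi = np.zeros((X.shape[0], n_features))
    for s, t in zip(ensemble.scales, ensemble.trees):
        for r in range(X.shape[0]):
            _shap_one_tree(t, X[r], phi[r], s)
    return phi


def mean_abs_attribution(phi: np.ndarray) -> np.ndarray:
    """Global importance: mean over samples of |per-sample attribution|."""
    return np.abs(phi).mean(axis=0)
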