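"""Flat tree-ensemble representation extracted from fitted models.

Supports scikit-learn decision trees / random forests / gradient boosting
and LightGBM boosters. Each tree is reduced to its set of leaves; a leaf is
described by its value and, per feature appearing on its root-to-leaf path,
the half-open interval (lo, hi] a sample must fall in to reach it (both
backends route "x <= threshold" to the left child).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Leaf:
    value: float
    features: np.ndarray   # unique feature indices on the path
    lo: np.ndarray         # open lower bounds, -inf if unbounded
    hi: np.ndarray         # closed upper bounds, +inf if unbounded


@dataclass
class FlatEnsemble:
    """Additive ensemble: prediction = base_offset + sum of leaf values."""

    leaves: list[Leaf]
    base_offset: float
    n_features: int

    def predict(self, X: np.ndarray) -> np.ndarray:
        """Reference prediction straight from the leaf intervals (slow path)."""
        X = np.asarray(X, dtype=float)
        out = np.full(X.shape[0], self.base_offset)
        for leaf in self.leaves:
            inside = np.ones(X.shape[0], dtype=bool)
            for f, lo, hi in zip(leaf.features, leaf.lo, leaf.hi):
                v = X[:, f]
                inside &= (v > lo) & (v <= hi)
            out[inside] += leaf.value
        return out


def _walk_arrays(children_left, children_right, feature, threshold, value,
                 scale: float, n_features: int) -> list[Leaf]:
    leaves: list[Leaf] = []

    def rec(node: int, lo: np.ndarray, hi: np.ndarray) -> None:
        if children_left[node] == -1:
            mask = np.isfinite(lo) | np.isfinite(hi)
            idx = np.flatnonzero(mask)
            leaves.append(Leaf(float(value[node]) * scale,
                               idx, lo[idx].copy(), hi[idx].copy()))
            return
        f, t = int(feature[node]), float(threshold[node])
        saved = hi[f]
        hi[f] = min(hi[f], t)
        rec(int(children_left[node]), lo, hi)
        hi[f] = saved
        saved = lo[f]
        lo[f] = max(lo[f], t)
        rec(int(children_right[node]), lo, hi)
        lo[f] = saved

    lo = np.full(n_features, -np.inf)
    hi = np.full(n_features, np.inf)
    rec(0, lo, hi)
    return leaves


def _walk_lgbm(node: dict, n_features: int, leaves: list[Leaf],
               lo: np.ndarray, hi: np.ndarray) -> None:
    if "leaf_value" in node:
        mask = np.isfinite(lo) | np.isfinite(hi)
        idx = np.flatnonzero(mask)
        leaves.append(Leaf(float(node["leaf_value"]), idx,
                           lo[idx].copy(), hi[idx].copy()))
        return
    if node.get("decision_type") != "<=":
        raise ValueError(f"unsupported split type {node.get('decision_type')!r}")
    f, t = int(node["split_feature"]), float(node["threshold"])
    saved = hi[f]
    hi[f] = min(hi[f], t)
    _walk_lgbm(node["left_child"], n_features, leaves, lo, hi)
    hi[f] = saved
    saved = lo[f]
    lo[f] = max(lo[f], t)
    _walk_lgbm(node["right_child"], n_features, leaves, lo, hi)
    lo[f] = saved


def extract_ensemble(model) -> FlatEnsemble:
    """Flatten a fitted tree model; raises ``TypeError`` if unsupported."""
    import sklearn.ensemble as ske
    import sklearn.tree as skt

    if hasattr(model, "booster_"):          # LGBMRegressor / LGBMClassifier
        model = model.booster_
    try:
        import lightgbm
        if isinstance(model, lightgbm.Booster):
            dump = model.dump_model()
            n_features = dump["max_feature_idx"] + 1
            leaves: list[Leaf] = []
            for tree in dump["tree_info"]:
                struct = tree["tree_structure"]
                if "leaf_value" in struct and "split_feature" not in struct:
                    # stump: constant tree
                    leaves.append(Leaf(float(struct["leaf_value"]),
                                       np.array([], dtype=int),
                                       np.array([]), np.array([])))
                    continue
                lo = np.full(n_features, -np.inf)
                hi = np.full(n_features, np.inf)
                _walk_lgbm(struct, n_features, leaves, lo, hi)
            return FlatEnsemble(leaves, 0.0, n_features)
    except ImportError:                      # pragma: no cover
        pass

    if isinstance(model, skt.DecisionTreeRegressor):
        t = model.tree_
        leaves = _walk_arrays(t.children_left, t.children_right, t.feature,
                              t.threshold, t.value.ravel(), 1.0, model.n_features_in_)
        return FlatEnsemble(leaves, 0.0, model.n_features_in_)

    if isinstance(model, ske.RandomForestRegressor):
        leaves = []
        k = len(model.estimators_)
        for est in model.estimators_:
            t = est.tree_
            leaves.extend(_walk_arrays(t.children_left, t.children_right,
                                       t.feature, t.threshold, t.value.ravel(),
                                       1.0 / k, model.n_features_in_))
        return FlatEnsemble(leaves, 0.0, model.n_features_in_)

    if isinstance(model, ske.GradientBoostingRegressor):
        leaves = []
        for stage in model.estimators_.ravel():
            t = stage.tree_
            leaves.extend(_walk_arrays(t.children_left, t.children_right,
                                       t.feature, t.threshold, t.value.ravel(),
                                       model.learning_rate, model.n_features_in_))
        base = float(model._raw_predict_init(
            np.zeros((1, model.n_features_in_))).ravel()[0])
        return FlatEnsemble(leaves, base, model.n_features_in_)

    raise TypeError(
        f"cannot extract trees from {type(model).__name__}; supported: "
        "LightGBM boosters and scikit-learn trees/forests/gradient boosting"
    )
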